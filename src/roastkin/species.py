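"""Species catalogue, packaged composition tables, and initial-state construction.

The model tracks 13 mass fractions (%w/w, dry basis): eight measured at the end
of the roast (caffeine CF, tartaric acid TA, acetic acid AA, citric acid CA,
trigonelline TR, pooled chlorogenic acids CGA, ferulic acid FA, lipids LP),
three sugars (SUC, FRU, GLC) and free amino acids (FAM) taken from literature
ranges, and a sink OTH absorbing everything not individually tracked so that
the state always sums to 100.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesCatalogue",
    "CompositionRange",
    "StateVector",
    "RoastDataset",
    "CATALOGUE",
    "load_reference_composition",
    "build_initial_state",
    "convert_mg_per_kg",
    "pool_cga",
    "load_roast_dataset",
    "load_reference_parameters",
    "PACKAGED_SAMPLES",
]

#: sample id -> variety for the four packaged single-origin roasts
PACKAGED_SAMPLES = {
    "mexico": "arabica",
    "rwanda": "arabica",
    "nicaragua": "robusta",
    "indonesia": "robusta",
}

_VARIETIES = ("arabica", "robusta")

#: the three chlorogenic-acid isomers quantified separately and pooled into CGA
CGA_ISOMERS = ("CGA_3", "CGA_5", "diCGA_35")


@dataclass(frozen=True)
class SpeciesCatalogue:
    """Fixed ordering of the 13 state variables; OTH is always last.

    The first eight species are the measured subset used in calibration.
    """

    species: tuple[str, ...] = (
        "CF", "TA", "AA", "CA", "TR", "CGA", "FA", "LP",
        "SUC", "FRU", "GLC", "FAM", "OTH",
    )
    n_measured: int = 8
    n_reactions: int = 15

    @property
    def measured(self) -> tuple[str, ...]:
        return self.species[: self.n_measured]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, code: str) -> int:
        """0-based position of a species code in the state vector."""
        try:
            return self.species.index(code)
        except ValueError:
            raise KeyError(f"unknown species code {code!r}; valid: {self.species}") from None


CATALOGUE = SpeciesCatalogue()


@dataclass(frozen=True)
class CompositionRange:
    """Literature range for one species in green coffee (%w/w dry basis)."""

    species: str
    low: float
    high: float
    variety: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.high <= 100.0):
            raise ValueError(
                f"{self.species}: need 0 <= low <= high <= 100, got ({self.low}, {self.high})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


@dataclass
class StateVector:
    """The 13 concentrations (%w/w dry basis) in catalogue order."""

    values: np.ndarray
    normalised: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (CATALOGUE.n_species,):
            raise ValueError(f"state vector must have shape (13,), got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("state vector entries must be non-negative")
        if self.normalised and abs(self.values.sum() - 100.0) > 1e-9:
            raise ValueError(f"normalised state must sum to 100, got {self.values.sum()!r}")

    def __getitem__(self, code: str) -> float:
        return float(self.values[CATALOGUE.index(code)])

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class RoastDataset:
    """One roast: variety, initial state, measured finals, thermal markers, horizon.

    ``measured`` maps the eight measured species codes to end-of-roast
    concentrations in %w/w dry basis (strictly positive — the calibration
    residuals are logarithms of concentration ratios).
    """

    sample_id: str
    variety: str
    initial_state: StateVector
    measured: dict[str, float]
    markers: "object"  # thermal.RoastMarkers; kept loose to avoid a cycle
    tau: float
    finals_table: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CATALOGUE.measured if c not in self.measured]
        if missing:
            raise ValueError(f"dataset {self.sample_id!r} missing measured species {missing}")
        for code, value in self.measured.items():
            if not value > 0:
                raise ValueError(
                    f"dataset {self.sample_id!r}: measured {code} = {value} must be "
                    "strictly positive (log-residuals require positive measurements)"
                )
        if self.markers is not None and abs(self.tau - self.markers.tau) > 1e-9:
            raise ValueError("tau must equal the time of the last (drop) marker")

    @property
    def measured_vector(self) -> np.ndarray:
        return np.array([self.measured[c] for c in CATALOGUE.measured])


def _packaged(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("roastkin.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_reference_composition(
    variety: str, path: str | Path | None = None
) -> list[CompositionRange]:
    """Green-bean composition ranges for one variety (%w/w dry basis).

    Reads the packaged literature table by default; ``path`` may point to a
    user CSV with the same schema (species, variety, low, high, unit).
    """
    if variety not in _VARIETIES:
        raise ValueError(f"unknown variety {variety!r}; valid varieties: {_VARIETIES}")
    table = pd.read_csv(path) if path is not None else _packaged("green_composition.csv")
    rows = table[table["variety"] == variety]
    ranges = [
        CompositionRange(r.species, float(r.low), float(r.high), variety)
        for r in rows.itertuples()
    ]
    expected = set(CATALOGUE.species) - {"OTH"}
    got = {r.species for r in ranges}
    if got != expected:
        raise ValueError(f"composition table for {variety!r} has species {got}, need {expected}")
    return ranges


def build_initial_state(ranges: list[CompositionRange]) -> StateVector:
    """Initial green-bean state: range midpoints plus the OTH complement to 100.

    Each listed species takes the midpoint of its literature range; the sink
    OTH is 100 minus the sum of the midpoints, so the state is normalised to a
    total mass of exactly 100 %w/w by construction.
    """
    by_code = {r.species: r for r in ranges}
    missing = [c for c in CATALOGUE.species if c != "OTH" and c not in by_code]
    if missing:
        raise ValueError(f"missing composition ranges for species {missing}")
    values = np.zeros(CATALOGUE.n_species)
    for code, rng in by_code.items():
        values[CATALOGUE.index(code)] = rng.midpoint
    midpoint_sum = values.sum()
    if midpoint_sum >= 100.0:
        raise ValueError(
            f"midpoint sum {midpoint_sum} >= 100: the OTH complement would be non-positive"
        )
    values[CATALOGUE.index("OTH")] = 100.0 - midpoint_sum
    return StateVector(values, normalised=True)


def convert_mg_per_kg(value: float) -> float:
    """Convert mg per kg of (dry) powder to %w/w: a pure factor of 1e4.

    The packaged end-of-roast table reports non-lipid analytes in mg/kg on a
    dry-weight basis; no moisture correction is applied (see docs/methods.md).
    """
    value = float(value)
    if value < 0:
        raise ValueError(f"concentration must be non-negative, got {value}")
    return value / 1.0e4


def pool_cga(cga3: float, cga5: float, dicga35: float) -> float:
    """Pool the three quantified chlorogenic-acid isomers into the lumped CGA.

    The model treats 3-CGA, 5-CGA and 3,5-diCGA as a single precursor pool of
    ferulic acid; the pooled concentration is their sum (units preserved).
    """
    parts = (cga3, cga5, dicga35)
    if any(p < 0 for p in parts):
        raise ValueError(f"isomer concentrations must be non-negative, got {parts}")
    return float(sum(parts))


def load_roast_dataset(
    sample_id: str,
    finals_path: str | Path | None = None,
    markers_path: str | Path | None = None,
    composition_path: str | Path | None = None,
) -> RoastDataset:
    """Assemble a complete roast dataset for one sample.

    For the four packaged samples the paper tables are used; user files with
    the same schemas can be supplied instead. Non-lipid analytes are converted
    from mg/kg by :func:`convert_mg_per_kg`, the CGA isomers are pooled, and
    lipids are taken directly in %w/w.
    """
    from . import thermal  # deferred: thermal imports nothing from here

    if finals_path is None and sample_id not in PACKAGED_SAMPLES:
        raise ValueError(
            f"unknown sample {sample_id!r}; packaged samples: {sorted(PACKAGED_SAMPLES)} "
            "(pass finals/markers/composition paths for user data)"
        )
    finals = (
        pd.read_csv(finals_path) if finals_path is not None else _packaged("roasted_finals.csv")
    )
    rows = finals[finals["sample"] == sample_id]
    if rows.empty:
        raise ValueError(f"no end-of-roast measurements found for sample {sample_id!r}")
    values = dict(zip(rows["analyte"], rows["mean"]))
    units = dict(zip(rows["analyte"], rows["unit"]))

    measured: dict[str, float] = {}
    for code in CATALOGUE.measured:
        if code == "CGA":
            try:
                isomers = [values[k] for k in CGA_ISOMERS]
            except KeyError as exc:
                raise ValueError(f"sample {sample_id!r} missing CGA isomer {exc}") from None
            measured["CGA"] = convert_mg_per_kg(pool_cga(*isomers))
        elif code == "LP":
            if "LP" not in values:
                raise ValueError(f"sample {sample_id!r} missing lipid measurement")
            if units["LP"] != "%w/w":
                raise ValueError(f"lipids must be reported in %w/w, got {units['LP']!r}")
            measured["LP"] = float(values["LP"])
        else:
            if code not in values:
                raise ValueError(f"sample {sample_id!r} missing measured species {code!r}")
            measured[code] = convert_mg_per_kg(values[code])

    variety = PACKAGED_SAMPLES.get(sample_id, "arabica")
    ranges = load_reference_composition(variety, path=composition_path)
    initial = build_initial_state(ranges)
    markers = thermal.load_markers(sample_id, path=markers_path)
    return RoastDataset(
        sample_id=sample_id,
        variety=variety,
        initial_state=initial,
        measured=measured,
        markers=markers,
        tau=markers.tau,
        finals_table=rows.reset_index(drop=True),
    )


def load_reference_parameters(sample_id: str, T_ref: float | None = None):
    """Packaged calibrated kinetic-parameter set for one sample.

    These are admissible reference points for forward simulation (e.g. the
    conservation diagnostics); ``T_ref`` defaults to the sample's yellow-phase
    marker temperature, the anchor under which the sets were derived.
    """
    from . import thermal
    from .kinetics import KineticParameters

    if sample_id not in PACKAGED_SAMPLES:
        raise ValueError(
            f"unknown sample {sample_id!r}; packaged samples: {sorted(PACKAGED_SAMPLES)}"
        )
    table = _packaged("reference_parameters.csv")
    rows = table[table["sample"] == sample_id].sort_values("reaction")
    if T_ref is None:
        T_ref = thermal.reference_temperature(thermal.load_markers(sample_id))
    return KineticParameters(
        rows["k_ref"].to_numpy(), rows["E_a"].to_numpy(), T_ref=T_ref
    )
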