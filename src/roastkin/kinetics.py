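"""The roasting reaction network, Arrhenius temperature dependence, and the
mass-conserving ODE right-hand side.

Fifteen reaction channels connect the 13 species. First-order channels are
simple thermal losses (or the sucrose inversion and CGA -> ferulic-acid steps);
second-order channels are the Maillard (sugar + FAM), acetic-acid-forming and
Strecker (lipid + FAM) reactions. Concentrations are mass fractions, so a
second-order channel A + FAM -> P consumes one mass unit of each precursor and
produces two units of P: the factor 2 is pure mass bookkeeping, not molar
stoichiometry. Every reaction's signed mass coefficients sum to zero, hence
the total mass sum(c) is a structural invariant of the flow.

Rate constants follow the Arrhenius law in reference form,

    k_i(T) = k_ref_i * exp[-(E_a_i / R) (1/T - 1/T_ref)],

with k_ref in s^-1 (first order) or (%w/w)^-1 s^-1 (second order), E_a in
kJ/mol and R = 8.314e-3 kJ/(mol K). The closed-form solutions of isolated
first-order, second-order and reversible channels at constant temperature are
provided as independent oracles for the numerical integrator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .species import CATALOGUE, StateVector

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "KineticParameters",
    "coffee_network",
    "GAS_CONSTANT_KJ",
    "DEFAULT_T_REF",
    "FIRST_ORDER_INDICES",
    "SECOND_ORDER_INDICES",
    "arrhenius_rate",
    "alpha_from_reference",
    "rhs",
    "total_mass",
    "first_order_solution",
    "second_order_solution",
    "reversible_solution",
]

#: universal gas constant in kJ/(mol K); activation energies are in kJ/mol
GAS_CONSTANT_KJ = 8.314e-3

#: default reference temperature for the Arrhenius reparameterisation (200 degC)
DEFAULT_T_REF = 473.15

#: 1-based reaction indices by kinetic order (the sets named by the rate bounds)
FIRST_ORDER_INDICES = frozenset({1, 2, 3, 4, 6, 9, 11, 12, 13, 14})
SECOND_ORDER_INDICES = frozenset({5, 7, 8, 10, 15})


@dataclass(frozen=True)
class Reaction:
    """One reaction channel with signed per-species mass coefficients.

    ``coefficients`` maps species code -> signed %w/w coefficient; products of
    second-order channels carry the duplication factor +2 so each channel is
    mass-balanced on its own.
    """

    index: int
    order: str  # "first" | "second"
    precursors: tuple[str, ...]
    product: str
    coefficients: dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        if self.order not in ("first", "second"):
            raise ValueError(f"reaction {self.index}: order must be first|second")
        n_expected = 1 if self.order == "first" else 2
        if len(self.precursors) != n_expected:
            raise ValueError(f"reaction {self.index}: {self.order}-order needs "
                             f"{n_expected} precursor(s), got {self.precursors}")
        balance = sum(self.coefficients.values())
        if abs(balance) > 1e-12:
            raise ValueError(f"reaction {self.index}: mass coefficients sum to {balance}, not 0")


def _reaction(index: int, precursors: tuple[str, ...], product: str) -> Reaction:
    order = "first" if len(precursors) == 1 else "second"
    coeff: dict[str, float] = {}
    for p in precursors:
        coeff[p] = coeff.get(p, 0.0) - 1.0
    coeff[product] = coeff.get(product, 0.0) + float(len(precursors))
    return Reaction(index, order, precursors, product, coeff)


@dataclass(frozen=True)
class ReactionNetwork:
    """The 15-channel roasting network over the fixed species catalogue."""

    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        if len(self.reactions) != CATALOGUE.n_reactions:
            raise ValueError(f"network must have {CATALOGUE.n_reactions} reactions")
        if [r.index for r in self.reactions] != list(range(1, CATALOGUE.n_reactions + 1)):
            raise ValueError("reactions must be indexed 1..15 in order")
        col_sums = self.stoichiometric_matrix().sum(axis=0)
        if np.any(np.abs(col_sums) > 1e-12):
            raise ValueError(f"stoichiometric column sums must vanish, got {col_sums}")

    def stoichiometric_matrix(self) -> np.ndarray:
        """Signed mass-coefficient matrix S, shape (13 species, 15 reactions)."""
        S = np.zeros((CATALOGUE.n_species, CATALOGUE.n_reactions))
        for j, r in enumerate(self.reactions):
            for code, coeff in r.coefficients.items():
                S[CATALOGUE.index(code), j] = coeff
        return S

    def precursor_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based state indices (i1, i2) per reaction; i2 = -1 for first order."""
        i1 = np.array([CATALOGUE.index(r.precursors[0]) for r in self.reactions])
        i2 = np.array(
            [CATALOGUE.index(r.precursors[1]) if r.order == "second" else -1
             for r in self.reactions]
        )
        return i1, i2

    def order_indices(self) -> tuple[frozenset[int], frozenset[int]]:
        first = frozenset(r.index for r in self.reactions if r.order == "first")
        second = frozenset(r.index for r in self.reactions if r.order == "second")
        return first, second

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "species": list(CATALOGUE.species),
            "reactions": [
                {
                    "index": r.index,
                    "order": r.order,
                    "precursors": list(r.precursors),
                    "product": r.product,
                    "coefficients": r.coefficients,
                }
                for r in self.reactions
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ReactionNetwork":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        if tuple(doc.get("species", ())) != CATALOGUE.species:
            raise ValueError("network document species do not match the catalogue ordering")
        reactions = tuple(
            Reaction(d["index"], d["order"], tuple(d["precursors"]), d["product"],
                     {k: float(v) for k, v in d["coefficients"].items()})
            for d in doc["reactions"]
        )
        return cls(reactions)


def coffee_network() -> ReactionNetwork:
    """The 15-channel coffee roasting network."""
    specs = [
        (1, ("CF",), "OTH"),          # caffeine thermal loss
        (2, ("TA",), "OTH"),          # tartaric acid thermal loss
        (3, ("SUC",), "FRU"),         # sucrose inversion -> fructose
        (4, ("SUC",), "GLC"),         # sucrose inversion -> glucose
        (5, ("FRU", "FAM"), "OTH"),   # Maillard, fructose branch
        (6, ("FRU",), "OTH"),         # fructose caramelisation
        (7, ("FRU", "FAM"), "AA"),    # acetic acid from fructose + amino acids
        (8, ("GLC", "FAM"), "OTH"),   # Maillard, glucose branch
        (9, ("GLC",), "OTH"),         # glucose caramelisation
        (10, ("GLC", "FAM"), "AA"),   # acetic acid from glucose + amino acids
        (11, ("CA",), "OTH"),         # citric acid decarboxylation
        (12, ("TR",), "OTH"),         # trigonelline degradation
        (13, ("CGA",), "FA"),         # lumped CGA pool -> ferulic acid
        (14, ("FA",), "OTH"),         # ferulic acid consumption
        (15, ("LP", "FAM"), "OTH"),   # Strecker: lipids + amino acids
    ]
    return ReactionNetwork(tuple(_reaction(*s) for s in specs))


@dataclass
class KineticParameters:
    """Reference rate constants, activation energies and reference temperature.

    The calibration unknown is theta = (k_ref_1..15, E_a_1..15).
    """

    k_ref: np.ndarray
    E_a: np.ndarray
    T_ref: float = DEFAULT_T_REF
    R: float = GAS_CONSTANT_KJ

    def __post_init__(self) -> None:
        self.k_ref = np.asarray(self.k_ref, dtype=float)
        self.E_a = np.asarray(self.E_a, dtype=float)
        n = CATALOGUE.n_reactions
        if self.k_ref.shape != (n,) or self.E_a.shape != (n,):
            raise ValueError(f"k_ref and E_a must have shape ({n},)")
        if np.any(self.k_ref < 0):
            raise ValueError("reference rate constants must be non-negative")
        if np.any(self.E_a < 0):
            raise ValueError("activation energies must be non-negative")
        if not self.T_ref > 0:
            raise ValueError("reference temperature must be positive (Kelvin)")

    @property
    def theta(self) -> np.ndarray:
        """Packed parameter vector (k_ref_1..15, E_a_1..15)."""
        return np.concatenate([self.k_ref, self.E_a])

    @classmethod
    def from_theta(cls, theta: np.ndarray, T_ref: float = DEFAULT_T_REF) -> "KineticParameters":
        theta = np.asarray(theta, dtype=float)
        n = CATALOGUE.n_reactions
        if theta.shape != (2 * n,):
            raise ValueError(f"theta must have shape ({2 * n},)")
        return cls(k_ref=theta[:n].copy(), E_a=theta[n:].copy(), T_ref=T_ref)

    def rates_at(self, T: float) -> np.ndarray:
        """All 15 rate constants at bean temperature T (Kelvin)."""
        if not T > 0:
            raise ValueError(f"temperature must be positive Kelvin, got {T}")
        return self.k_ref * np.exp(-(self.E_a / self.R) * (1.0 / T - 1.0 / self.T_ref))


def arrhenius_rate(pars: KineticParameters, i: int, T: float) -> float:
    """Rate constant k_i(T) from the reference form of the Arrhenius law (1-based i)."""
    if not 1 <= i <= CATALOGUE.n_reactions:
        raise ValueError(f"reaction index must be in 1..{CATALOGUE.n_reactions}, got {i}")
    if not T > 0:
        raise ValueError(f"temperature must be positive Kelvin, got {T}")
    j = i - 1
    return float(pars.k_ref[j] * np.exp(-(pars.E_a[j] / pars.R) * (1.0 / T - 1.0 / pars.T_ref)))


def alpha_from_reference(pars: KineticParameters, i: int) -> float:
    """Pre-exponential factor alpha_i = k_ref_i exp(E_a_i / (R T_ref)).

    Substituting alpha_i into the standard law alpha exp(-E_a/(R T)) reproduces
    :func:`arrhenius_rate` at every temperature.
    """
    if not 1 <= i <= CATALOGUE.n_reactions:
        raise ValueError(f"reaction index must be in 1..{CATALOGUE.n_reactions}, got {i}")
    j = i - 1
    return float(pars.k_ref[j] * np.exp(pars.E_a[j] / (pars.R * pars.T_ref)))


def rhs(
    state: np.ndarray | StateVector,
    T: float,
    pars: KineticParameters,
    network: ReactionNetwork | None = None,
) -> np.ndarray:
    """Time derivatives of the 13 concentrations at bean temperature T (Kelvin).

    Inputs below zero are clamped to zero before forming the reaction fluxes,
    so integrator micro-undershoots cannot generate spurious negative rates.
    The component sum is zero up to floating-point cancellation.
    """
    c = state.values if isinstance(state, StateVector) else np.asarray(state, dtype=float)
    if c.shape != (CATALOGUE.n_species,):
        raise ValueError(f"state must have shape (13,), got {c.shape}")
    network = network if network is not None else coffee_network()
    k = pars.rates_at(T)
    c_pos = np.maximum(c, 0.0)
    i1, i2 = network.precursor_indices()
    fluxes = k * c_pos[i1] * np.where(i2 >= 0, c_pos[np.maximum(i2, 0)], 1.0)
    return network.stoichiometric_matrix() @ fluxes


def total_mass(state: np.ndarray | StateVector) -> float:
    """Total dry mass M_tot: the sum of the 13 concentrations, %w/w."""
    c = state.values if isinstance(state, StateVector) else np.asarray(state, dtype=float)
    return float(c.sum())


def first_order_solution(A0: float, k: float, t: float) -> float:
    """Product concentration [B](t) of an isolated A -> B channel: A0 (1 - e^{-kt})."""
    if A0 < 0 or k < 0 or np.any(np.asarray(t) < 0):
        raise ValueError("A0, k and t must be non-negative")
    return A0 * -np.expm1(-k * t)


def second_order_solution(A0: float, B0: float, k: float, t: float) -> float:
    """Product concentration [C](t) of an isolated A + B -> C channel.

    Closed form requires A0 != B0; [C] is bounded by the limiting reactant.
    """
    if A0 < 0 or B0 < 0 or k < 0 or np.any(np.asarray(t) < 0):
        raise ValueError("A0, B0, k and t must be non-negative")
    if A0 == B0:
        raise ValueError("closed form assumes distinct initial concentrations (A0 != B0)")
    x = k * (B0 - A0) * t
    if x >= 0:  # evaluate with e^{-x} so large exponents cannot overflow
        em = np.exp(-x)
        return A0 * B0 * (1.0 - em) / (B0 - A0 * em)
    e = np.exp(x)
    return A0 * B0 * (e - 1.0) / (B0 * e - A0)


def reversible_solution(A0: float, k1: float, k2: float, t: float) -> float:
    """Product concentration [B](t) of a reversible A <-> B channel.

    [B] relaxes to the equilibrium A0 k1/(k1+k2) at rate k1+k2. Not part of
    the roasting network; retained as an analytic oracle.
    """
    if A0 < 0 or k1 < 0 or k2 < 0 or np.any(np.asarray(t) < 0):
        raise ValueError("A0, k1, k2 and t must be non-negative")
    if k1 + k2 == 0:
        raise ValueError("k1 + k2 must be positive (no dynamics otherwise)")
    return (A0 * k1 / (k1 + k2)) * -np.expm1(-(k1 + k2) * t)
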