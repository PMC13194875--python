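"""Bean temperature profile from roast markers.

The roaster log provides five markers per batch: charge temperature, turning
point, onset of the yellow phase, first crack, and drop. The charge reading is
the drum (not bean) temperature, so the bean profile interpolates the assumed
25 degC start at t = 0 together with the four bean markers, using monotone
shape-preserving piecewise cubic Hermite interpolation (pchip). On monotone
marker temperatures this gives a C1, non-overshooting, non-decreasing T_b(t).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "RoastMarkers",
    "TemperatureProfile",
    "parse_clock_time",
    "load_markers",
    "build_temperature_profile",
    "evaluate_temperature",
    "reference_temperature",
    "CELSIUS_OFFSET",
]

CELSIUS_OFFSET = 273.15

#: marker roles in chronological order; only the last four are bean temperatures
MARKER_ROLES = ("charge", "turning_point", "yellow", "first_crack", "drop")

_CLOCK_RE = re.compile(r"^(\d+):([0-5]\d)$")


def parse_clock_time(text: str) -> float:
    """Parse an ``m:ss`` / ``mm:ss`` roast clock time into seconds."""
    m = _CLOCK_RE.match(str(text).strip())
    if m is None:
        raise ValueError(f"malformed clock time {text!r}; expected m:ss with seconds < 60")
    return 60.0 * int(m.group(1)) + int(m.group(2))


@dataclass(frozen=True)
class RoastMarkers:
    """Temperature markers of one roast: (role, time s, temp degC) triples."""

    sample_id: str
    roles: tuple[str, ...]
    times: tuple[float, ...]
    temps_c: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.roles != MARKER_ROLES:
            raise ValueError(f"markers must carry roles {MARKER_ROLES}, got {self.roles}")
        # charge shares t = 0 with the synthetic bean start; bean markers strictly increase
        bean_times = self.times[1:]
        if any(t2 <= t1 for t1, t2 in zip(bean_times, bean_times[1:])):
            raise ValueError(f"bean marker times must be strictly increasing: {bean_times}")
        if not all(np.isfinite(self.temps_c)):
            raise ValueError("marker temperatures must be finite")

    @property
    def tau(self) -> float:
        """Roast horizon: the drop time, in seconds."""
        return self.times[-1]

    @property
    def charge_temp_c(self) -> float:
        """Drum temperature at charge; metadata, not part of the bean profile."""
        return self.temps_c[0]

    @property
    def yellow_temp_c(self) -> float:
        """Bean temperature at the onset of the yellow phase, degC."""
        return self.temps_c[MARKER_ROLES.index("yellow")]


def reference_temperature(markers: RoastMarkers) -> float:
    """Arrhenius reference temperature for a roast, in Kelvin.

    The reference rate constants are anchored at the yellow-phase marker
    temperature of the batch (onset of the main reactive phase, 150-156 degC
    for the packaged roasts). Anchoring mid-ramp keeps the rate-constant
    bounds dimensionally meaningful across the whole roast; see
    docs/methods.md for why this particular anchor is used.
    """
    return markers.yellow_temp_c + CELSIUS_OFFSET


def load_markers(sample_id: str, path: str | Path | None = None) -> RoastMarkers:
    """Load the markers of one sample from the packaged table or a user CSV."""
    if path is not None:
        table = pd.read_csv(path)
    else:
        ref = importlib.resources.files("roastkin.data").joinpath("roast_markers.csv")
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p)
    rows = table[table["sample"] == sample_id]
    if rows.empty:
        raise ValueError(f"no roast markers found for sample {sample_id!r}")
    by_role = {r.marker: r for r in rows.itertuples()}
    missing = [role for role in MARKER_ROLES if role not in by_role]
    if missing:
        raise ValueError(f"sample {sample_id!r} missing markers {missing}")
    times = tuple(parse_clock_time(by_role[role].clock_time) for role in MARKER_ROLES)
    temps = tuple(float(by_role[role].temp_C) for role in MARKER_ROLES)
    return RoastMarkers(sample_id, MARKER_ROLES, times, temps)


class TemperatureProfile:
    """Evaluable bean-temperature function T_b(t) on [0, tau], in Kelvin.

    Interpolates five nodes — the synthetic (0 s, start_temp) point plus the
    turning-point, yellow, first-crack and drop markers — with pchip. The
    interpolant is built in degC; evaluation adds 273.15.
    """

    def __init__(self, node_times: np.ndarray, node_temps_c: np.ndarray) -> None:
        node_times = np.asarray(node_times, dtype=float)
        node_temps_c = np.asarray(node_temps_c, dtype=float)
        if node_times.ndim != 1 or node_times.shape != node_temps_c.shape:
            raise ValueError("node times and temperatures must be 1-d arrays of equal length")
        if np.any(np.diff(node_times) <= 0):
            raise ValueError(f"node times must be strictly increasing: {node_times}")
        self.node_times = node_times
        self.node_temps_c = node_temps_c
        self._interp = PchipInterpolator(node_times, node_temps_c, extrapolate=False)
        self.tau = float(node_times[-1])

    def __call__(self, t) -> np.ndarray | float:
        """Bean temperature in Kelvin at time(s) t; no extrapolation."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.tau):
            raise ValueError(f"time outside the roast interval [0, {self.tau}]")
        out = self._interp(t) + CELSIUS_OFFSET
        return float(out) if out.ndim == 0 else out

    @property
    def breakpoints(self) -> np.ndarray:
        """Interpolation breakpoints (seconds); exposed for the fast ODE kernel."""
        return self._interp.x

    @property
    def coefficients(self) -> np.ndarray:
        """Local cubic coefficients, shape (4, nseg), highest power first (degC)."""
        return self._interp.c

    def export(self, n: int = 400) -> pd.DataFrame:
        """Dense (t s, T degC) table for plotting the thermal history."""
        t = np.linspace(0.0, self.tau, n)
        return pd.DataFrame({"time_s": t, "temp_C": np.asarray(self(t)) - CELSIUS_OFFSET})


def build_temperature_profile(
    markers: RoastMarkers, start_temp_c: float = 25.0
) -> TemperatureProfile:
    """Build T_b(t) from roast markers with the 25 degC bean-start assumption.

    The charge marker is excluded (it reads the drum wall, and conflicts with
    the ambient bean start at the same t = 0); the profile passes through the
    start point and the four bean markers exactly.
    """
    times = np.concatenate(([0.0], markers.times[1:]))
    temps = np.concatenate(([start_temp_c], markers.temps_c[1:]))
    return TemperatureProfile(times, temps)


def evaluate_temperature(profile: TemperatureProfile, t) -> np.ndarray | float:
    """Bean temperature in Kelvin at time(s) t (functional form of profile(t))."""
    return profile(t)
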