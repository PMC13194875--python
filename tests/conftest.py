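"""Shared fixtures: packaged datasets, reference parameter sets, and a lazy
session-wide cache of full multistart calibrations (they are minutes each, and
several acceptance properties inspect the same fit)."""

from __future__ import annotations

import numpy as np
import pytest

import roastkin as rk

SAMPLES = list(rk.PACKAGED_SAMPLES)

#: a fixed, coffee-plausible synthetic truth used by the self-consistency
#: checks: moderate first-order losses, a fast ferulic-acid turnover, weak
#: Maillard channels, all comfortably inside the admissible box.
SYNTH_KREF = np.array([
    3e-5, 2e-4, 3e-4, 5e-4,            # CF, TA, SUC->FRU, SUC->GLC
    2e-6, 1e-3, 4e-5, 2e-6,            # Maillard FRU, caramel FRU, AA(FRU), Maillard GLC
    5e-4, 1e-4, 4e-4, 4e-4,            # caramel GLC, AA(GLC), CA, TR
    4e-4, 2e-2, 5e-4,                  # CGA->FA, FA, Strecker LP
])
SYNTH_EA = np.array([110.0, 105.0, 100.0, 100.0, 110.0, 105.0, 100.0, 120.0,
                     110.0, 60.0, 100.0, 100.0, 100.0, 100.0, 105.0])
SYNTH_THETA = np.concatenate([SYNTH_KREF, SYNTH_EA])


@pytest.fixture(scope="session")
def datasets() -> dict[str, rk.RoastDataset]:
    return {s: rk.load_roast_dataset(s) for s in SAMPLES}


@pytest.fixture(scope="session")
def profiles(datasets) -> dict[str, rk.TemperatureProfile]:
    return {s: rk.build_temperature_profile(d.markers) for s, d in datasets.items()}


@pytest.fixture(scope="session")
def reference_parameters() -> dict[str, rk.KineticParameters]:
    """Packaged calibrated parameter sets, one per sample (admissible points
    used for forward-simulation checks), at the per-roast reference anchor."""
    return {s: rk.load_reference_parameters(s) for s in SAMPLES}


class _CalibrationCache:
    """Lazy per-sample full calibrations (S = 30, seed = 1)."""

    def __init__(self, datasets):
        self._datasets = datasets
        self._results: dict[str, rk.CalibrationResult] = {}

    def __getitem__(self, sample: str) -> rk.CalibrationResult:
        if sample not in self._results:
            self._results[sample] = rk.calibrate(self._datasets[sample], S=30, seed=1)
        return self._results[sample]


@pytest.fixture(scope="session")
def calibrations(datasets) -> _CalibrationCache:
    return _CalibrationCache(datasets)


@pytest.fixture(scope="session")
def synthetic_dataset(datasets) -> rk.RoastDataset:
    """Noise-free synthetic roast generated from the fixed truth above."""
    return rk.generate_synthetic_dataset(
        SYNTH_THETA, "arabica", datasets["rwanda"].markers, noise_sd=0.0
    )


@pytest.fixture(scope="session")
def synthetic_calibration(synthetic_dataset) -> rk.CalibrationResult:
    """Self-consistency fit: S = 5 starts against the noise-free synthetic data."""
    return rk.calibrate(synthetic_dataset, S=5, seed=7)
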