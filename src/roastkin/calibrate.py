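"""Calibration of the kinetic parameters from end-of-roast measurements.

The unknown is theta = (k_ref_1..15, E_a_1..15), constrained to a box: rate
constants at the reference temperature are positive and bounded above (0.1 s^-1
first order, 0.001 (%w/w)^-1 s^-1 second order), activation energies lie in
40-150 kJ/mol. The objective is the squared 2-norm of the log-residuals

    r_j(theta) = log(c_j(tau) / cbar_j(tau)),   j over the 8 measured species,

which is scale-invariant and approximates the relative error near a good fit.
With 30 unknowns against 8 residuals the problem is underdetermined, so a
damped (Levenberg-Marquardt) Gauss-Newton iteration is used, every trial
iterate being projected componentwise onto the box, and the whole local search
is restarted from S randomly sampled feasible points; the best converged point
wins (ties broken by lowest start index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticParameters, ReactionNetwork, coffee_network
from .simulate import SolverSettings, _integrate, _kernel_args
from .species import CATALOGUE, RoastDataset, StateVector
from .thermal import TemperatureProfile, build_temperature_profile, reference_temperature

__all__ = [
    "CalibrationBounds",
    "OptimiserOptions",
    "StartRecord",
    "CalibrationResult",
    "log_residuals",
    "objective",
    "project_to_bounds",
    "sample_starts",
    "calibrate",
    "final_error_report",
]

logger = logging.getLogger(__name__)

_N = CATALOGUE.n_reactions  # 15 reactions -> 30 parameters


@dataclass(frozen=True)
class CalibrationBounds:
    """Componentwise box for theta = (k_ref_1..15, E_a_1..15)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        if lo.shape != (2 * _N,) or up.shape != (2 * _N,):
            raise ValueError(f"bounds must have shape ({2 * _N},)")
        if np.any(lo > up):
            raise ValueError("lower bounds must not exceed upper bounds")

    @classmethod
    def default(
        cls,
        network: ReactionNetwork | None = None,
        k_max_first: float = 0.1,
        k_max_second: float = 0.001,
        ea_min: float = 40.0,
        ea_max: float = 150.0,
        k_floor: float = 1e-12,
    ) -> "CalibrationBounds":
        """The standard admissible box, with a strictly positive k_ref floor.

        The admissible set is open at k_ref = 0; the floor keeps logarithmic
        start sampling and the Arrhenius evaluation well-defined.
        """
        network = network if network is not None else coffee_network()
        first, _second = network.order_indices()
        k_up = np.array(
            [k_max_first if i in first else k_max_second for i in range(1, _N + 1)]
        )
        lower = np.concatenate([np.full(_N, k_floor), np.full(_N, ea_min)])
        upper = np.concatenate([k_up, np.full(_N, ea_max)])
        return cls(lower, upper)

    def contains(self, theta: np.ndarray, rtol: float = 1e-12) -> bool:
        theta = np.asarray(theta, dtype=float)
        slack = rtol * np.maximum(np.abs(self.upper), 1.0)
        return bool(np.all(theta >= self.lower - slack) and np.all(theta <= self.upper + slack))


@dataclass(frozen=True)
class OptimiserOptions:
    """Damped Gauss-Newton settings (least-squares solver conventions)."""

    max_iterations: int = 300
    max_fun_evals: int = 50_000
    step_tol: float = 1e-10
    fun_tol: float = 1e-10
    fd_rel_step: float = 1e-6
    lambda0: float = 1e-3
    lambda_up: float = 5.0
    lambda_down: float = 5.0
    lambda_max: float = 1e14


@dataclass
class StartRecord:
    """Outcome of one local minimisation."""

    index: int
    theta0: np.ndarray = field(repr=False)
    theta: np.ndarray = field(repr=False)
    objective: float = np.inf
    iterations: int = 0
    n_evaluations: int = 0
    termination: str = "not_run"


@dataclass
class CalibrationResult:
    """Best fit over all starts, with full per-start records."""

    theta: np.ndarray
    objective: float
    residuals: np.ndarray
    sim_final: np.ndarray  # full 13-species state at tau
    starts: list[StartRecord]
    seed: int
    n_starts: int
    T_ref: float
    errors_pct: dict[str, float]

    @property
    def parameters(self) -> KineticParameters:
        return KineticParameters.from_theta(self.theta, T_ref=self.T_ref)


def log_residuals(sim_final: np.ndarray | StateVector, measured: dict[str, float]) -> np.ndarray:
    """Log-residual vector over the measured species, in catalogue order."""
    c = sim_final.values if isinstance(sim_final, StateVector) else np.asarray(sim_final)
    r = np.empty(CATALOGUE.n_measured)
    for j, code in enumerate(CATALOGUE.measured):
        if code not in measured:
            raise ValueError(f"measured map missing species {code!r}")
        sim_j = float(c[CATALOGUE.index(code)])
        meas_j = float(measured[code])
        if sim_j <= 0 or meas_j <= 0:
            raise ValueError(
                f"log-residual undefined for {code}: simulated {sim_j}, measured {meas_j}"
            )
        r[j] = np.log(sim_j / meas_j)
    return r


def project_to_bounds(theta: np.ndarray, bounds: CalibrationBounds) -> np.ndarray:
    """Componentwise median of (lower, theta, upper): min(max(theta, l), u)."""
    return np.minimum(np.maximum(np.asarray(theta, dtype=float), bounds.lower), bounds.upper)


def _make_residual_fn(
    dataset: RoastDataset,
    profile: TemperatureProfile,
    T_ref: float,
    settings: SolverSettings,
    network: ReactionNetwork,
):
    """Closure theta -> residual vector, with precomputed kernel arrays."""
    i1, i2 = network.precursor_indices()
    i1 = np.ascontiguousarray(i1)
    i2 = np.ascontiguousarray(i2)
    S = np.ascontiguousarray(network.stoichiometric_matrix())
    xb = np.ascontiguousarray(profile.breakpoints)
    coef = np.ascontiguousarray(profile.coefficients)
    inv_tref = 1.0 / T_ref
    R = 8.314e-3
    c0 = dataset.initial_state.values.copy()
    measured = dataset.measured_vector
    t_span = np.array([0.0, profile.tau])
    n_meas = measured.size

    def residual(theta: np.ndarray) -> np.ndarray:
        kref = np.ascontiguousarray(theta[:_N])
        ea = np.ascontiguousarray(theta[_N:])
        y, _ = _integrate(
            c0, t_span, (kref, ea, inv_tref, R, xb, coef, i1, i2, S), settings
        )
        final = np.maximum(y[-1, :n_meas], 1e-300)
        return np.log(final / measured)

    return residual


def objective(
    theta: np.ndarray,
    dataset: RoastDataset,
    profile: TemperatureProfile | None = None,
    T_ref: float | None = None,
    settings: SolverSettings | None = None,
    network: ReactionNetwork | None = None,
) -> float:
    """F(theta) = ||r(theta)||_2^2 after a full forward simulation.

    ``T_ref`` defaults to the roast's yellow-phase marker temperature.
    """
    profile = profile if profile is not None else build_temperature_profile(dataset.markers)
    T_ref = T_ref if T_ref is not None else reference_temperature(dataset.markers)
    settings = settings or SolverSettings()
    network = network if network is not None else coffee_network()
    r = _make_residual_fn(dataset, profile, T_ref, settings, network)(
        np.asarray(theta, dtype=float)
    )
    return float(r @ r)


def sample_starts(
    bounds: CalibrationBounds,
    S: int,
    rng: np.random.Generator,
    log_span: float = 1e6,
) -> np.ndarray:
    """Sample S feasible start vectors.

    Rate constants span orders of magnitude, so k_ref components are drawn
    log-uniformly over [max(lower, upper/log_span), upper]; activation
    energies are drawn uniformly over their interval.
    """
    if S < 1:
        raise ValueError("need at least one start")
    k_lo = np.maximum(bounds.lower[:_N], bounds.upper[:_N] / log_span)
    k_hi = bounds.upper[:_N]
    # one start drawn at a time, so the first S' starts of a larger S match a
    # smaller run with the same seed (monotone-multistart property)
    starts = np.empty((S, 2 * _N))
    for s in range(S):
        u = rng.random(_N)
        starts[s, :_N] = np.exp(np.log(k_lo) + u * (np.log(k_hi) - np.log(k_lo)))
        starts[s, _N:] = rng.uniform(bounds.lower[_N:], bounds.upper[_N:])
    return starts


def _fd_jacobian(residual, x, r0, bounds, rel_step, counter):
    """Forward finite-difference Jacobian of the residual vector.

    The step is scaled per component (relative to |x_j|, floored by a fraction
    of the box width) and is taken without projection: the model is defined in
    a neighbourhood of the box, only the iterates themselves must be feasible.
    """
    n = x.size
    J = np.empty((r0.size, n))
    width = bounds.upper - bounds.lower
    h = rel_step * np.maximum(np.abs(x), 1e-3 * width)
    for j in range(n):
        xj = x.copy()
        xj[j] += h[j]
        rj = residual(xj)
        counter[0] += 1
        J[:, j] = (rj - r0) / h[j]
    return J


def _projected_lm(residual, x0, bounds, opts: OptimiserOptions):
    """Levenberg-Marquardt with componentwise projection of every trial iterate."""
    lb, ub = bounds.lower, bounds.upper
    width = np.maximum(ub - lb, 1e-300)
    x = np.minimum(np.maximum(np.asarray(x0, dtype=float), lb), ub)
    counter = [0]
    r = residual(x)
    counter[0] += 1
    F = float(r @ r)
    lam = opts.lambda0
    termination = "max_iterations"
    it = 0
    for it in range(1, opts.max_iterations + 1):
        if counter[0] + x.size >= opts.max_fun_evals:
            termination = "max_fun_evals"
            break
        J = _fd_jacobian(residual, x, r, bounds, opts.fd_rel_step, counter)
        JtJ = J.T @ J
        g = J.T @ r
        diag = np.diag(JtJ)
        D = np.maximum(diag, 1e-14 * diag.max() + 1e-300)
        accepted = False
        while counter[0] < opts.max_fun_evals:
            A = JtJ + lam * np.diag(D)
            try:
                step = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(A, -g, rcond=None)[0]
            x_new = np.minimum(np.maximum(x + step, lb), ub)
            r_new = residual(x_new)
            counter[0] += 1
            F_new = float(r_new @ r_new)
            if np.isfinite(F_new) and F_new < F:
                accepted = True
                break
            lam *= opts.lambda_up
            if lam > opts.lambda_max:
                break
        if not accepted:
            termination = "no_progress"
            break
        dx = x_new - x
        dF = F - F_new
        x, r, F = x_new, r_new, F_new
        lam = max(lam / opts.lambda_down, 1e-12)
        scaled_step = np.max(np.abs(dx) / np.maximum(np.abs(x), 1e-3 * width))
        if scaled_step <= opts.step_tol:
            termination = "step_tol"
            break
        if dF <= opts.fun_tol * max(F, 1e-300):
            termination = "fun_tol"
            break
    return x, r, F, it, counter[0], termination


def calibrate(
    dataset: RoastDataset,
    bounds: CalibrationBounds | None = None,
    S: int = 30,
    seed: int = 0,
    options: OptimiserOptions | None = None,
    T_ref: float | None = None,
    settings: SolverSettings | None = None,
    network: ReactionNetwork | None = None,
    profile: TemperatureProfile | None = None,
) -> CalibrationResult:
    """Multistart bound-constrained calibration of the 30 kinetic parameters.

    Runs S independent projected Levenberg-Marquardt descents from randomly
    sampled feasible starts and returns the best converged point. Reproducible
    for a fixed seed; ties between equally good starts go to the lowest index.
    ``T_ref`` defaults to the roast's yellow-phase marker temperature.
    """
    network = network if network is not None else coffee_network()
    T_ref = T_ref if T_ref is not None else reference_temperature(dataset.markers)
    bounds = bounds if bounds is not None else CalibrationBounds.default(network)
    options = options or OptimiserOptions()
    settings = settings or SolverSettings()
    profile = profile if profile is not None else build_temperature_profile(dataset.markers)
    residual = _make_residual_fn(dataset, profile, T_ref, settings, network)

    rng = np.random.default_rng(seed)
    theta0s = sample_starts(bounds, S, rng)
    records: list[StartRecord] = []
    for s_idx in range(S):
        rec = StartRecord(index=s_idx, theta0=theta0s[s_idx], theta=theta0s[s_idx])
        try:
            x, r, F, iters, nfev, term = _projected_lm(residual, theta0s[s_idx], bounds, options)
            rec.theta, rec.objective = x, F
            rec.iterations, rec.n_evaluations, rec.termination = iters, nfev, term
        except Exception as exc:  # solver breakdown on a pathological start
            rec.termination = f"error: {exc}"
        logger.info(
            "start %d/%d: F=%.6e after %d iterations (%s)",
            s_idx + 1, S, rec.objective, rec.iterations, rec.termination,
        )
        records.append(rec)

    finite = [rec for rec in records if np.isfinite(rec.objective)]
    if not finite:
        raise RuntimeError(
            "all calibration starts failed; per-start diagnostics: "
            + "; ".join(f"#{rec.index}: {rec.termination}" for rec in records)
        )
    best = min(finite, key=lambda rec: (rec.objective, rec.index))

    # re-simulate at the winner for the full final state and the error table
    args = _kernel_args(profile, KineticParameters.from_theta(best.theta, T_ref), network)
    y, _ = _integrate(
        dataset.initial_state.values, np.array([0.0, profile.tau]), args, settings
    )
    sim_final = np.maximum(y[-1], 0.0)
    r_best = log_residuals(np.maximum(sim_final, 1e-300), dataset.measured)
    errors = {
        code: abs(sim_final[CATALOGUE.index(code)] - dataset.measured[code])
        / dataset.measured[code] * 100.0
        for code in CATALOGUE.measured
    }
    return CalibrationResult(
        theta=best.theta,
        objective=best.objective,
        residuals=r_best,
        sim_final=sim_final,
        starts=records,
        seed=seed,
        n_starts=S,
        T_ref=T_ref,
        errors_pct=errors,
    )


def final_error_report(result: CalibrationResult, dataset: RoastDataset) -> dict[str, float]:
    """Relative percentage error |c_j(tau) - cbar_j(tau)| / cbar_j(tau) * 100.

    Reported as magnitudes for each measured species.
    """
    return {
        code: abs(result.sim_final[CATALOGUE.index(code)] - dataset.measured[code])
        / dataset.measured[code] * 100.0
        for code in CATALOGUE.measured
    }
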