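"""Compiled inner kernels for the ODE right-hand side and its Jacobian.

The calibration evaluates the model thousands of times (each residual is a
full stiff integration), so the per-step work — piecewise-cubic temperature
lookup, Arrhenius rates, sparse stoichiometric accumulation — is jitted. The
kernels take plain arrays; the readable reference implementation lives in
:mod:`roastkin.kinetics` and the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numba as nb
import numpy as np

CELSIUS_OFFSET = 273.15


@nb.njit(fastmath=False)
def eval_pchip_c(t, xb, coef):
    """Evaluate the piecewise cubic (degC) at t, clamped to the node span.

    LSODA may probe marginally outside [0, tau] while stepping; clamping is
    equivalent to holding the boundary temperatures, which the nodes pin.
    """
    if t < xb[0]:
        t = xb[0]
    elif t > xb[-1]:
        t = xb[-1]
    nseg = xb.shape[0] - 1
    seg = nseg - 1
    for j in range(nseg):
        if t < xb[j + 1]:
            seg = j
            break
    dt = t - xb[seg]
    v = coef[0, seg]
    for k in range(1, coef.shape[0]):
        v = v * dt + coef[k, seg]
    return v


@nb.njit(fastmath=False)
def _rate_constants(t, kref, ea, inv_tref, R, xb, coef, out):
    T = eval_pchip_c(t, xb, coef) + CELSIUS_OFFSET
    inv_T = 1.0 / T
    for i in range(kref.shape[0]):
        out[i] = kref[i] * np.exp(-(ea[i] / R) * (inv_T - inv_tref))


@nb.njit(fastmath=False)
def rhs_ode(y, t, kref, ea, inv_tref, R, xb, coef, i1, i2, S):
    """f(c, t): signed mass fluxes accumulated through the stoichiometry S.

    Negative state entries (integrator undershoot) are clamped to zero before
    forming products, so fluxes never take the wrong sign.
    """
    n_r = kref.shape[0]
    n_s = S.shape[0]
    k = np.empty(n_r)
    _rate_constants(t, kref, ea, inv_tref, R, xb, coef, k)
    dy = np.zeros(n_s)
    for r in range(n_r):
        c1 = y[i1[r]]
        if c1 < 0.0:
            c1 = 0.0
        if i2[r] >= 0:
            c2 = y[i2[r]]
            if c2 < 0.0:
                c2 = 0.0
            f = k[r] * c1 * c2
        else:
            f = k[r] * c1
        if f != 0.0:
            for s in range(n_s):
                if S[s, r] != 0.0:
                    dy[s] += S[s, r] * f
    return dy


@nb.njit(fastmath=False)
def jac_ode(y, t, kref, ea, inv_tref, R, xb, coef, i1, i2, S):
    """d f / d c, consistent with the clamped right-hand side."""
    n_r = kref.shape[0]
    n_s = S.shape[0]
    k = np.empty(n_r)
    _rate_constants(t, kref, ea, inv_tref, R, xb, coef, k)
    J = np.zeros((n_s, n_s))
    for r in range(n_r):
        a = i1[r]
        c1 = y[a]
        pos1 = c1 > 0.0
        if not pos1:
            c1 = 0.0
        if i2[r] >= 0:
            b = i2[r]
            c2 = y[b]
            pos2 = c2 > 0.0
            if not pos2:
                c2 = 0.0
            d1 = k[r] * c2 if pos1 else 0.0
            d2 = k[r] * c1 if pos2 else 0.0
            for s in range(n_s):
                if S[s, r] != 0.0:
                    J[s, a] += S[s, r] * d1
                    J[s, b] += S[s, r] * d2
        else:
            d1 = k[r] if pos1 else 0.0
            for s in range(n_s):
                if S[s, r] != 0.0:
                    J[s, a] += S[s, r] * d1
    return J
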