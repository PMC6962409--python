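"""Hodgkin-Huxley activation/inactivation rate curves.

All curves are functions of the dimensionless membrane potential v = V/mV
and return rates in kHz (= 1/ms), so they compose directly with the
package's internal (mV, ms, nS, pF) unit system.

Three of the six curves have removable singularities (a 0/0 of the form
u/(e^{u/s}-1) as u -> 0); these are evaluated through the analytic limit
c*s when |u| < 1e-9 to avoid a visible branch discontinuity.
"""

from __future__ import annotations

import numpy as np

_SINGULARITY_TOL = 1e-9


def _ratio_rate(c: float, u, s: float):
    """c * u / (e^{u/s} - 1), with the limit c*s at u -> 0."""
    u = np.asarray(u)
    small = np.abs(u) < _SINGULARITY_TOL
    u_safe = np.where(small, 1.0, u)
    with np.errstate(over="ignore"):
        val = c * u_safe / np.expm1(u_safe / s)
    return np.where(small, c * s, val)


def alpha_m(v):
    return _ratio_rate(0.32, -50.0 - np.asarray(v), 4.0)


def beta_m(v):
    return _ratio_rate(0.28, 23.0 + np.asarray(v), 5.0)


def alpha_h(v):
    with np.errstate(over="ignore"):
        return 0.128 * np.exp((-46.0 - np.asarray(v)) / 18.0)


def beta_h(v):
    with np.errstate(over="ignore"):
        return 4.0 / (1.0 + np.exp((-23.0 - np.asarray(v)) / 5.0))


def alpha_n(v):
    return _ratio_rate(0.032, -48.0 - np.asarray(v), 5.0)


def beta_n(v):
    with np.errstate(over="ignore"):
        return 0.5 * np.exp((-53.0 - np.asarray(v)) / 40.0)


RATE_FUNCTIONS = {
    "alpha_m": alpha_m,
    "beta_m": beta_m,
    "alpha_h": alpha_h,
    "beta_h": beta_h,
    "alpha_n": alpha_n,
    "beta_n": beta_n,
}


def rate_curve(kind: str, v):
    """Evaluate one of the six named rate curves at v = V/mV (rate in kHz)."""
    try:
        fn = RATE_FUNCTIONS[kind]
    except KeyError:
        raise ValueError(
            f"unknown rate curve {kind!r}; expected one of {sorted(RATE_FUNCTIONS)}"
        ) from None
    out = fn(v)
    return float(out) if np.ndim(out) == 0 else out


def steady_state_gate(kind: str, v):
    """Fixed point x_inf = alpha/(alpha+beta) of the gating ODE at potential v.

    ``kind`` is one of "m", "h", "n".
    """
    if kind not in ("m", "h", "n"):
        raise ValueError(f"unknown gate {kind!r}; expected 'm', 'h' or 'n'")
    a = np.asarray(RATE_FUNCTIONS[f"alpha_{kind}"](v), dtype=float)
    b = np.asarray(RATE_FUNCTIONS[f"beta_{kind}"](v), dtype=float)
    out = a / (a + b)
    return float(out) if np.ndim(out) == 0 else out
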