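"""Leaky integrator of looming events and its coupling to turning gain.

The internal state ``s(t)`` accumulates neighbor-evoked looming input
with first-order dynamics::

    tau * ds/dt = s_rest - s(t) + r * Input(t)

where ``Input(t)`` is the maximal per-step increase in retinal occupancy
over all visible objects (deg/step), ``r`` a dimensionless input scale
and ``tau`` a very slow time constant (hours).  With ``tau`` of 6 h the
process operates mostly in its initial linear regime over experimental
time scales.  The state linearly attenuates the occupancy-response
slope: ``a' = a * (1 - (s - s_start) / D)``, floored at 0, so that
``s = s_start`` leaves the baseline gain and ``s = s_start + D``
suppresses the social response completely.

``s`` is clamped to ``[s_rest, s_start + D]``; the clamp keeps the
effective slope within ``[0, a * (1 + s_start / D)]`` and forbids a
response reversal, which is never observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._kernels import leaky_trace

__all__ = [
    "IntegratorParams",
    "InternalState",
    "step_integrator",
    "analytic_state",
    "effective_slope",
    "integrate_series",
    "fit_decay_tau",
]


@dataclass(frozen=True)
class IntegratorParams:
    """Parameters of the loom integrator (times in seconds internally)."""

    tau_s: float = 6.0 * 3600.0
    r: float = 13.0
    s_rest: float = 0.0
    s_start: float = 0.6
    D: float = 0.19

    def __post_init__(self):
        if not self.tau_s > 0:
            raise ValueError("tau must be > 0")
        if not self.D > 0:
            raise ValueError("D must be > 0")

    @classmethod
    def from_hours(cls, tau_hr: float = 6.0, **kw) -> "IntegratorParams":
        return cls(tau_s=tau_hr * 3600.0, **kw)

    @property
    def s_min(self) -> float:
        return self.s_rest

    @property
    def s_max(self) -> float:
        return self.s_start + self.D

    def clamp(self, s: float) -> float:
        return float(min(max(s, self.s_min), self.s_max))


@dataclass(frozen=True)
class InternalState:
    """Value of the integrator at time ``t_s`` since run start."""

    s: float
    t_s: float = 0.0


def step_integrator(
    state: InternalState, input_value: float, dt_s: float, params: IntegratorParams
) -> InternalState:
    """One forward-Euler update of the integrator, clamped to its bounds.

    Requires ``0 < dt_s < tau`` (the explicit scheme is unstable
    otherwise; in practice ``dt`` is 1/50 s against a 6 h ``tau``).
    """
    if not dt_s > 0:
        raise ValueError("dt must be > 0")
    if dt_s >= params.tau_s:
        raise ValueError("dt >= tau: unstable discretization")
    s = state.s + (dt_s / params.tau_s) * (
        params.s_rest - state.s + params.r * float(input_value)
    )
    return InternalState(s=params.clamp(s), t_s=state.t_s + dt_s)


def analytic_state(
    s0: float, elapsed_s: float, input_const: float, params: IntegratorParams
) -> float:
    """Exact solution under constant input (unclamped); the test oracle.

    ``s(t) = s_eq + (s0 - s_eq) * exp(-t/tau)`` with
    ``s_eq = s_rest + r * I``.
    """
    s_eq = params.s_rest + params.r * input_const
    return float(s_eq + (s0 - s_eq) * np.exp(-elapsed_s / params.tau_s))


def effective_slope(a_base: float, state: InternalState | float, params: IntegratorParams) -> float:
    """State-modulated occupancy-response slope ``a' = a(1-(s-s_start)/D)``, >= 0."""
    if a_base < 0:
        raise ValueError("a_base must be >= 0")
    s = state.s if isinstance(state, InternalState) else float(state)
    return max(0.0, a_base * (1.0 - (s - params.s_start) / params.D))


def integrate_series(
    s0: float,
    inputs,
    dt_s: float,
    params: IntegratorParams,
    record_stride: int = 1,
) -> np.ndarray:
    """Euler-integrate a whole input series (deg/step) at once.

    ``inputs`` may be an array (one value per step) or a scalar paired
    with an integer step count via ``np.full``.  Returns the recorded
    state at every ``record_stride``-th step (state *after* that step).
    """
    if dt_s >= params.tau_s:
        raise ValueError("dt >= tau: unstable discretization")
    inp = np.asarray(inputs, dtype=float)
    return leaky_trace(
        float(s0), inp, dt_s, params.tau_s, params.r, params.s_rest,
        params.s_min, params.s_max, int(record_stride),
    )


def fit_decay_tau(t_s: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of ``s(t) = s(0) * exp(-t/tau)`` to a zero-input trace.

    Returns ``(tau_s, r_squared)``.
    """
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(s, dtype=float)
    s0 = y[0] if y[0] != 0 else 1.0

    def model(tt, tau):
        return s0 * np.exp(-tt / tau)

    popt, _ = curve_fit(model, t, y, p0=[max(t[-1], 1.0)], maxfev=10000)
    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(popt[0]), r2
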