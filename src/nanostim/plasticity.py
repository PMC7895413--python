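"""Event-driven short-term synaptic plasticity.

Every synapse's dynamic weight depends only on the *presynaptic* spike train,
so for homogeneous class parameters the per-synapse resource variable is an
exact time-shifted copy of one master variable per presynaptic neuron.  This
module evolves those master variables with closed-form exponential relaxation
between spikes (exact, no integration error) and computes the amplitude factor
reported at each spike.

Conventions at a spike arriving at time t (following the printed update order):

* depressing synapse: amplitude factor = R(t-); afterwards R <- R * (1 - U_se).
* facilitating RS→SOM synapse: after relaxing both variables to t, the
  facilitation variable jumps first, u(t+) = u(t-) + (1 - u(t-)) U; the
  amplitude factor is R(t-) * u(t+) / U_b; the resource is then depleted with
  the *pre-jump* release probability, R <- R - u(t-) R(t-).
* transmission failure (RS→SOM only): the spike is transmitted with
  probability 1 - p_f(t-); afterwards p_f drops by G(p_f, delta_p_f, p_min),
  a full jump delta_p_f clipped so that p_f never falls below p_min.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import (FACIL, PlasticityParams, ParameterError)


@dataclass(frozen=True)
class PlasticityState:
    """Master variables of one presynaptic neuron for one synapse class."""
    R: float = 1.0      # available resources, (0, 1]
    u: float = 0.0      # release probability (facilitating class only)
    p_f: float = 0.0    # failure probability (RS→SOM only)
    t: float = -np.inf  # time of last update [ms]


def rest_state(params: PlasticityParams) -> PlasticityState:
    return PlasticityState(R=1.0, u=params.U_b, p_f=params.p_f_rest, t=-np.inf)


def std_advance(state: PlasticityState, dt: float, tau_D: float) -> PlasticityState:
    """Relax the resource variable toward 1 over an interspike interval."""
    if dt < 0:
        raise ParameterError("cannot advance plasticity state backwards in time")
    decay = np.exp(-dt / tau_D) if np.isfinite(dt) else 0.0
    return replace(state, R=1.0 - (1.0 - state.R) * decay, t=state.t + dt)


def std_on_spike(state: PlasticityState, U_se: float):
    """Register a spike on a depressing synapse; returns (state, amplitude factor)."""
    factor = state.R
    return replace(state, R=state.R * (1.0 - U_se)), factor


def facilitation_advance(state: PlasticityState, dt: float,
                         params: PlasticityParams) -> PlasticityState:
    if dt < 0:
        raise ParameterError("cannot advance plasticity state backwards in time")
    dR = np.exp(-dt / params.tau_D) if np.isfinite(dt) else 0.0
    dF = np.exp(-dt / params.tau_F) if np.isfinite(dt) else 0.0
    dp = np.exp(-dt / params.tau_f_fail) if np.isfinite(dt) else 0.0
    return PlasticityState(
        R=1.0 - (1.0 - state.R) * dR,
        u=params.U_b + (state.u - params.U_b) * dF,
        p_f=params.p_f_rest + (state.p_f - params.p_f_rest) * dp,
        t=state.t + dt,
    )


def failure_jump(p_f: float, delta_p_f: float, p_min: float) -> float:
    """Piecewise-linear downward jump G of the failure rate after a spike."""
    if p_f <= p_min:
        return 0.0
    if p_f < p_min + delta_p_f:
        return p_f - p_min
    return delta_p_f


def facilitation_on_spike(state: PlasticityState, params: PlasticityParams):
    """Register a spike on the facilitating class; returns (state, amplitude factor).

    The returned factor excludes the stochastic failure gate; combine with
    :func:`failure_on_spike` (or the mean factor ``1 - p_f``) as needed.
    """
    u_pre, R_pre = state.u, state.R
    u_post = u_pre + (1.0 - u_pre) * params.U
    factor = R_pre * u_post / params.U_b
    new = replace(state, u=u_post, R=R_pre - u_pre * R_pre,
                  p_f=state.p_f - failure_jump(state.p_f, params.delta_p_f,
                                               params.p_min))
    return new, factor


def failure_on_spike(state: PlasticityState, params: PlasticityParams,
                     rng: np.random.Generator):
    """Draw the binary transmission gate at a spike; returns (state, transmitted).

    The failure probability read before the spike gates transmission; the
    post-spike jump of p_f is applied by :func:`facilitation_on_spike`.
    """
    transmitted = bool(rng.random() < 1.0 - state.p_f)
    return state, transmitted


def mean_depression_factor(rate_hz, tau_D_ms: float, U_se: float):
    """Stationary mean resource level of a depressing synapse driven at ``rate_hz``.

    R̄(r) = 1 / (1 + tau_D * U_se * r), with tau_D converted to seconds.
    """
    rate = np.asarray(rate_hz, dtype=float)
    if np.any(rate < 0):
        raise ParameterError("presynaptic rate must be non-negative")
    return 1.0 / (1.0 + (tau_D_ms / 1000.0) * U_se * rate)


def depression_factors(spike_times: np.ndarray, params: PlasticityParams,
                       R0: float = 1.0, t0: float = -np.inf) -> np.ndarray:
    """Amplitude factors R(t-) for every spike of one presynaptic train."""
    times = np.asarray(spike_times, dtype=float)
    out = np.empty(times.size)
    R, t_last = R0, t0
    for j, t in enumerate(times):
        decay = np.exp(-(t - t_last) / params.tau_D) if np.isfinite(t_last) else 0.0
        R = 1.0 - (1.0 - R) * decay
        out[j] = R
        R *= 1.0 - params.U_se
        t_last = t
    return out


def facilitation_factors(spike_times: np.ndarray, params: PlasticityParams,
                         rng: np.random.Generator | None = None,
                         mean_failures: bool = False):
    """Amplitude factors of the facilitating RS→SOM class for one spike train.

    Returns ``(factors, p_f_pre)`` where ``factors`` includes the stochastic
    failure gate if ``rng`` is given, the mean gate ``1 - p_f(t-)`` if
    ``mean_failures`` is true, and no gate otherwise.  ``p_f_pre`` holds the
    failure probability seen by each spike.
    """
    if params.mode != FACIL:
        raise ParameterError("facilitation_factors needs the facilitating class")
    times = np.asarray(spike_times, dtype=float)
    factors = np.empty(times.size)
    p_pre = np.empty(times.size)
    state = rest_state(params)
    for j, t in enumerate(times):
        dt = t - state.t if np.isfinite(state.t) else np.inf
        state = replace(facilitation_advance(state, dt, params), t=t)
        p_pre[j] = state.p_f
        state, f = facilitation_on_spike(state, params)
        if rng is not None:
            f *= 1.0 if rng.random() < 1.0 - p_pre[j] else 0.0
        elif mean_failures:
            f *= 1.0 - p_pre[j]
        factors[j] = f
    return factors, p_pre
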