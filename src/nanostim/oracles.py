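"""Independent oracles and small deterministic fixtures for validation.

Everything here re-derives quantities by brute force — per-synapse state
variables instead of the per-neuron master variables, Monte-Carlo simulation
instead of quadrature, Bernoulli sampling instead of the closed-form
detection model — and deliberately shares no code path with the
implementations it is used to validate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .params import FACIL, STATIC, STRONG, WEAK, PlasticityParams


@dataclass
class SynapseTrajectory:
    """Event-table of one synapse's own state variables at its arrival times."""
    arrival_times: np.ndarray
    R: np.ndarray        # resources read by each arriving spike (pre-jump)
    u: np.ndarray        # post-jump release probability (facilitating only)
    p_f: np.ndarray      # pre-jump failure probability (facilitating only)
    factor: np.ndarray   # amplitude factor of each arriving spike

    def to_text(self, path: str) -> None:
        """Delimited-text event table (t, R, u, p_f, factor) for debugging."""
        header = "t_ms\tR\tu\tp_f\tfactor"
        np.savetxt(path, np.column_stack(
            [self.arrival_times, self.R, self.u, self.p_f, self.factor]),
            header=header, fmt="%.9g", delimiter="\t")


def per_synapse_plasticity_oracle(spike_times: np.ndarray, delay: float,
                                  params: PlasticityParams) -> SynapseTrajectory:
    """Brute-force simulation of one synapse's own plasticity equations.

    The synapse sees arrivals at ``spike_times + delay`` and integrates its
    own resource/facilitation/failure variables spike by spike, written out
    independently of the master-variable implementation.
    """
    arrivals = np.asarray(spike_times, dtype=float) + delay
    n = arrivals.size
    R_out = np.ones(n)
    u_out = np.zeros(n)
    p_out = np.zeros(n)
    f_out = np.ones(n)
    R = 1.0
    u = params.U_b
    p = params.p_f_rest
    t_prev = None
    for j, t in enumerate(arrivals):
        if t_prev is not None:
            dt = t - t_prev
            if params.mode in (STRONG, WEAK, FACIL):
                R = 1.0 - (1.0 - R) * np.exp(-dt / params.tau_D)
            if params.mode == FACIL:
                u = params.U_b + (u - params.U_b) * np.exp(-dt / params.tau_F)
                p = params.p_f_rest + (p - params.p_f_rest) \
                    * np.exp(-dt / params.tau_f_fail)
        R_out[j] = R
        p_out[j] = p
        if params.mode in (STRONG, WEAK):
            f_out[j] = R
            R = R - params.U_se * R
        elif params.mode == FACIL:
            u_new = u + (1.0 - u) * params.U
            f_out[j] = R * u_new / params.U_b
            R = R - u * R
            # downward jump of the failure rate, floored at p_min
            if p > params.p_min + params.delta_p_f:
                p = p - params.delta_p_f
            elif p > params.p_min:
                p = params.p_min
            u = u_new
        u_out[j] = u
        t_prev = t
    return SynapseTrajectory(arrival_times=arrivals, R=R_out, u=u_out,
                             p_f=p_out, factor=f_out)


def poisson_spike_train(rate_hz: float, T_ms: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson spike train on (0, T_ms)."""
    n = rng.poisson(rate_hz * T_ms / 1000.0)
    return np.sort(rng.uniform(0.0, T_ms, size=n))


def time_averaged_resources_mc(rate_hz: float, params: PlasticityParams,
                               T_ms: float, seed: int,
                               sample_dt: float = 5.0) -> float:
    """Monte-Carlo time average of the depression variable under Poisson drive.

    Samples R(t) on a regular grid (by PASTA, the grid average equals the
    average seen by Poisson spikes); independent check of the closed-form
    stationary mean 1/(1 + tau_D U_se r).
    """
    rng = np.random.default_rng(seed)
    spikes = poisson_spike_train(rate_hz, T_ms, rng)
    grid = np.arange(sample_dt, T_ms, sample_dt)
    R = 1.0
    t_prev = 0.0
    vals = np.empty(grid.size)
    j = 0
    for gi, g in enumerate(grid):
        while j < spikes.size and spikes[j] <= g:
            R = 1.0 - (1.0 - R) * np.exp(-(spikes[j] - t_prev) / params.tau_D)
            R *= 1.0 - params.U_se
            t_prev = spikes[j]
            j += 1
        vals[gi] = 1.0 - (1.0 - R) * np.exp(-(g - t_prev) / params.tau_D)
    # discard an initial transient of a few recovery times
    skip = int(min(5 * params.tau_D / sample_dt, vals.size // 2))
    return float(np.mean(vals[skip:]))


def shot_noise_lif_oracle(a_e: float, a_i: float, R_e: float, R_i: float,
                          mu0: float, tau_m: float, tau_ref: float,
                          T_ms: float = 500_000.0, seed: int = 0,
                          dt: float = 0.01, v_T: float = 20.0,
                          v_R: float = 10.0):
    """Empirical rate of a shot-noise-driven LIF neuron, with standard error.

    Long single-neuron Monte-Carlo simulation (numba, Mersenne-Twister stream,
    independent of the network kernel's generator).
    """
    rate = _kernel.lif_shot_noise_rate_mc(seed, tau_m, v_T, v_R, tau_ref, mu0,
                                          a_e, a_i, R_e, R_i, T_ms, dt)
    n_spk = rate * T_ms / 1000.0
    se = rate / np.sqrt(max(n_spk, 1.0))
    return rate, se


def discrete_detection_oracle(p0: float, delta_p, n: int, n_mc: int,
                              seed: int = 0):
    """Monte-Carlo twin of the independent-draw detection model.

    Simulates ``n_mc`` catch and stimulus trials of ``n`` independent draws;
    a trial triggers the detector if any draw crosses.  Returns
    ``(fp, cd, effect_size)``.
    """
    rng = np.random.default_rng(seed)
    delta_p = np.atleast_1d(np.asarray(delta_p, dtype=float))
    p_stim = np.full(n, p0)
    p_stim[:delta_p.size] += delta_p
    u_catch = rng.random((n_mc, n))
    u_stim = rng.random((n_mc, n))
    fp = float(np.mean((u_catch > p0).any(axis=1)))
    cd = float(np.mean((u_stim > p_stim[None, :]).any(axis=1)))
    return fp, cd, cd - fp


def tiny_plasticity_fixture(n_neurons: int = 10, T_ms: float = 2000.0,
                            rate_hz: float = 20.0, seed: int = 42):
    """Spike trains and heterogeneous delays for the master-variable identity test."""
    rng = np.random.default_rng(seed)
    trains = [poisson_spike_train(rate_hz, T_ms, rng) for _ in range(n_neurons)]
    delays = rng.uniform(0.5, 1.0, size=n_neurons)
    return trains, delays
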