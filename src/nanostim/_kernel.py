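"""Numba integration kernel for the spiking network.

Exponential-Euler update of every leaky integrate-and-fire neuron on a fixed
grid (default dt = 0.05 ms), with

* delayed synaptic spike delivery through a ring buffer (delays quantized to
  the step, minimum one step),
* short-term plasticity evolved event-driven through per-neuron master
  variables (one resource variable per depression class plus the facilitation
  and failure variables of the RS→SOM class), evaluated at the presynaptic
  spike time as the printed weight equations prescribe,
* external Poisson shot noise with exponentially distributed jump amplitudes,
  generated per neuron by next-event sampling,
* spike-frequency adaptation as a spike-triggered current decaying between
  spikes, and a voltage clamp at the reset value during refractoriness
  (synaptic input arriving while clamped is discarded).

All quantities reaching the kernel are plain arrays; unit conventions are
those of :mod:`nanostim.params`.  A spike with (signed, plasticity-scaled)
weight J produces an instantaneous voltage jump of J mV in the target.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# fast inline RNG: xorshift128+ uniforms and a ziggurat exponential sampler.
# The network kernel uses this stream; the Monte-Carlo oracles below use
# numba's own Mersenne-Twister RNG so that oracle and implementation share no
# random-number code path.
# ---------------------------------------------------------------------------

def _build_ziggurat_tables():
    """256-level ziggurat tables for the unit exponential (Marsaglia/Tsang)."""
    m = 2.0**32
    de = 7.697117470131487
    ve = 3.949659822581572e-3
    ke = np.zeros(256, dtype=np.uint64)
    we = np.zeros(256)
    fe = np.zeros(256)
    q = ve / np.exp(-de)
    ke[0] = np.uint64((de / q) * m)
    ke[1] = 0
    we[0] = q / m
    we[255] = de / m
    fe[0] = 1.0
    fe[255] = np.exp(-de)
    te = de
    for i in range(254, 0, -1):
        de = -np.log(ve / de + np.exp(-de))
        ke[i + 1] = np.uint64((de / te) * m)
        te = de
        fe[i] = np.exp(-de)
        we[i] = de / m
    return ke, we, fe


_ZIG_KE, _ZIG_WE, _ZIG_FE = _build_ziggurat_tables()
_ZIG_TAIL = 7.697117470131487


@njit(cache=True, inline="always")
def _next_u64(state):
    x = state[0]
    y = state[1]
    state[0] = y
    x ^= x << np.uint64(23)
    state[1] = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
    return state[1] + y


@njit(cache=True, inline="always")
def _uniform(state):
    return (_next_u64(state) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True)
def _std_exponential(state):
    while True:
        r = _next_u64(state) & np.uint64(0xFFFFFFFF)
        idx = np.int64(r & np.uint64(0xFF))
        x = np.float64(r) * _ZIG_WE[idx]
        if r < _ZIG_KE[idx]:
            return x
        if idx == 0:
            return _ZIG_TAIL - np.log(1.0 - _uniform(state))
        if _ZIG_FE[idx] + _uniform(state) * (_ZIG_FE[idx - 1] - _ZIG_FE[idx]) \
                < np.exp(-x):
            return x


@njit(cache=True)
def _seed_state(seed):
    """SplitMix64 expansion of a trial seed into a nonzero xorshift128+ state."""
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = w ^ (w >> np.uint64(31))
    if state[0] == 0 and state[1] == 0:
        state[0] = np.uint64(1)
    return state


def plasticity_vector(strong, weak, facil) -> np.ndarray:
    """Pack the three class parameter sets into the kernel's flat vector."""
    return np.array([
        strong.tau_D, strong.U_se,
        weak.tau_D, weak.U_se,
        facil.tau_D, facil.tau_F, facil.U_b, facil.U,
        facil.p_f_rest, facil.delta_p_f, facil.p_min, facil.tau_f_fail,
    ])


@njit(cache=True)
def _failure_jump(p_f, dpf, pmin):
    if p_f <= pmin:
        return 0.0
    if p_f < pmin + dpf:
        return p_f - pmin
    return dpf


@njit(cache=True)
def run_trial(seed,
              tau_m, v_T, ref_steps, tau_a, delta_a, rm,
              ext_rate, ext_jump, bias,
              indptr, syn_tgt, syn_w, syn_dstep, syn_class,
              plast, stim_neuron, stim_mv,
              n_steps, dt, v_reset,
              spk_neuron, spk_step):
    """Integrate one trial; fills the spike buffers, returns the spike count.

    Returns -1 if the spike buffer overflows (caller enlarges and reruns;
    the per-trial seed makes the rerun identical).
    """
    state = _seed_state(seed)
    N = tau_m.size
    tauD_s, Use_s = plast[0], plast[1]
    tauD_w, Use_w = plast[2], plast[3]
    tauD_f, tauF, Ub, Uj = plast[4], plast[5], plast[6], plast[7]
    pf_rest, dpf, pmin, tau_pf = plast[8], plast[9], plast[10], plast[11]

    decay_v = np.exp(-dt / tau_m)
    decay_a = np.exp(-dt / tau_a)

    buf_len = 1
    for s in range(syn_dstep.size):
        if syn_dstep[s] + 1 > buf_len:
            buf_len = syn_dstep[s] + 1
    inbuf = np.zeros((buf_len, N))

    v = np.empty(N)
    a = np.zeros(N)
    refrac_until = np.full(N, -1, dtype=np.int64)
    next_ext = np.empty(N)
    ext_scale = np.empty(N)  # mean inter-event interval in ms
    for k in range(N):
        v[k] = _uniform(state) * v_T[k]
        if ext_rate[k] > 0.0:
            ext_scale[k] = 1000.0 / ext_rate[k]
            next_ext[k] = ext_scale[k] * _std_exponential(state)
        else:
            ext_scale[k] = 0.0
            next_ext[k] = np.inf

    # plasticity master variables, at rest
    Rs = np.ones(N)
    Rw = np.ones(N)
    Rf = np.ones(N)
    uf = np.full(N, Ub)
    pf = np.full(N, pf_rest)
    last_t = np.full(N, -1.0e12)

    n_spk = 0
    max_spk = spk_neuron.size
    for step in range(n_steps):
        t_next = (step + 1) * dt
        row = step % buf_len
        stim = 0.0
        if stim_neuron >= 0:
            stim = stim_mv[step]
        for k in range(N):
            # external shot noise accumulated over this step
            noise = 0.0
            while next_ext[k] < t_next:
                noise += ext_jump[k] * _std_exponential(state)
                next_ext[k] += ext_scale[k] * _std_exponential(state)
            if step < refrac_until[k]:
                v[k] = v_reset
                a[k] *= decay_a[k]
                inbuf[row, k] = 0.0
                continue
            mu = bias - rm[k] * a[k]
            if k == stim_neuron:
                mu += stim
            vk = mu + (v[k] - mu) * decay_v[k] + inbuf[row, k] + noise
            inbuf[row, k] = 0.0
            a[k] *= decay_a[k]
            if vk < v_T[k]:
                v[k] = vk
                continue
            # --- spike ---
            if n_spk >= max_spk:
                return -1
            spk_neuron[n_spk] = k
            spk_step[n_spk] = step
            n_spk += 1
            v[k] = v_reset
            refrac_until[k] = step + 1 + ref_steps[k]
            a[k] += delta_a[k]
            t_sp = t_next
            dtl = t_sp - last_t[k]
            # advance masters to the spike time, read pre-jump values
            es = np.exp(-dtl / tauD_s)
            Rs_pre = 1.0 - (1.0 - Rs[k]) * es
            Rs[k] = Rs_pre * (1.0 - Use_s)
            ew = np.exp(-dtl / tauD_w)
            Rw_pre = 1.0 - (1.0 - Rw[k]) * ew
            Rw[k] = Rw_pre * (1.0 - Use_w)
            ef = np.exp(-dtl / tauD_f)
            Rf_pre = 1.0 - (1.0 - Rf[k]) * ef
            u_pre = Ub + (uf[k] - Ub) * np.exp(-dtl / tauF)
            pf_pre = pf_rest + (pf[k] - pf_rest) * np.exp(-dtl / tau_pf)
            u_post = u_pre + (1.0 - u_pre) * Uj
            fac_factor = Rf_pre * u_post / Ub
            Rf[k] = Rf_pre * (1.0 - u_pre)
            uf[k] = u_post
            pf[k] = pf_pre - _failure_jump(pf_pre, dpf, pmin)
            last_t[k] = t_sp
            # deliver outgoing spikes
            for s in range(indptr[k], indptr[k + 1]):
                c = syn_class[s]
                if c == 0:
                    amp = syn_w[s]
                elif c == 1:
                    amp = syn_w[s] * Rs_pre
                elif c == 2:
                    amp = syn_w[s] * Rw_pre
                else:
                    if _uniform(state) < pf_pre:
                        continue  # transmission failure
                    amp = syn_w[s] * fac_factor
                inbuf[(step + syn_dstep[s]) % buf_len, syn_tgt[s]] += amp
    return n_spk


@njit(cache=True)
def lif_shot_noise_rate_mc(seed, tau_m, v_T, v_reset, tau_ref, mu0,
                           a_e, a_i, rate_e, rate_i, T_ms, dt):
    """Monte-Carlo firing rate of one LIF neuron under shot-noise drive.

    Excitatory/inhibitory Poisson streams (rates in Hz) with exponentially
    distributed jump amplitudes a_e/a_i (mV); constant input mu0 = R_m I_0.
    Independent oracle for the closed-form shot-noise rate formula.
    """
    np.random.seed(seed)
    n_steps = int(T_ms / dt)
    decay = np.exp(-dt / tau_m)
    ref_steps = int(np.ceil(tau_ref / dt))
    v = 0.0
    next_e = np.random.exponential(1000.0 / rate_e) if rate_e > 0 else np.inf
    next_i = np.random.exponential(1000.0 / rate_i) if rate_i > 0 else np.inf
    refrac = -1
    n_spk = 0
    for step in range(n_steps):
        t_next = (step + 1) * dt
        jump = 0.0
        while next_e < t_next:
            jump += np.random.exponential(a_e)
            next_e += np.random.exponential(1000.0 / rate_e)
        while next_i < t_next:
            jump -= np.random.exponential(a_i)
            next_i += np.random.exponential(1000.0 / rate_i)
        if step < refrac:
            v = v_reset
            continue
        v = mu0 + (v - mu0) * decay + jump
        if v >= v_T:
            n_spk += 1
            v = v_reset
            refrac = step + 1 + ref_steps
    return n_spk / (T_ms / 1000.0)
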