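"""Trial simulation of the recurrent network and basic spike statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .network import NetworkRealization
from .params import (FACILITATING, RS, STRONG_DEPRESSION, WEAK_DEPRESSION,
                     ConfigurationError, SimConfig)
from .stimuli import CATCH, StimulusSpec


@dataclass
class TrialRecord:
    """Spike trains of one trial; times in ms relative to stimulus onset."""
    neuron: np.ndarray       # int32 spike emitter ids
    time: np.ndarray         # float64 spike times [ms]
    t_start: float           # trial span [t_start, t_end]
    t_end: float
    dt: float
    stimulus: StimulusSpec
    trial_seed: int
    pop: np.ndarray          # per-neuron population codes (shared reference)
    stim_target: int
    r_ext_th: float | None = None  # per-trial thalamic rate if modulated

    def spikes_of(self, neuron_id: int) -> np.ndarray:
        return self.time[self.neuron == neuron_id]

    def population_mask(self, pop_code: int) -> np.ndarray:
        return self.pop[self.neuron] == pop_code

    def to_text(self, path: str, trial_id: int = 0) -> None:
        """Delimited-text export: one spike per row (trial, neuron, pop, t_ms)."""
        with open(path, "w") as fh:
            fh.write("trial\tneuron\tpop\tt_ms\n")
            for n, t in zip(self.neuron, self.time):
                fh.write(f"{trial_id}\t{n}\t{int(self.pop[n])}\t{t:.3f}\n")


def save_batch(records: list[TrialRecord], path: str) -> None:
    """Write a trial batch to one container of named arrays (.npz)."""
    arrays = {}
    meta = []
    for j, rec in enumerate(records):
        arrays[f"neuron_{j}"] = rec.neuron
        arrays[f"time_{j}"] = rec.time
        meta.append([rec.t_start, rec.t_end, rec.dt, rec.trial_seed])
    arrays["meta"] = np.asarray(meta)
    arrays["pop"] = records[0].pop
    np.savez_compressed(path, **arrays)


def _trial_seed_stream(master_seed: int, n: int) -> np.ndarray:
    """Counter-based derivation of independent per-trial 31-bit seeds."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n, dtype=np.uint64) % (2**31 - 1)).astype(np.int64)


def simulate_trial(realization: NetworkRealization,
                   stimulus: StimulusSpec = CATCH,
                   trial_seed: int = 0,
                   sim: SimConfig | None = None,
                   t_start: float | None = None,
                   t_end: float | None = None,
                   r_ext_th: float | None = None) -> TrialRecord:
    """Forward-integrate one trial of the frozen realization.

    The stimulus current is injected into ``realization.stim_target`` only.
    ``r_ext_th`` overrides the thalamic background rate for this trial (the
    slow-nonstationarity proxy); initial conditions and shot noise are drawn
    from ``trial_seed``.
    """
    sim = sim or SimConfig()
    t0 = -sim.T_idle if t_start is None else t_start
    t1 = sim.T_end if t_end is None else t_end
    dt = sim.dt
    n_steps = int(round((t1 - t0) / dt))
    n_pre = int(round(-t0 / dt))

    dstep = np.maximum(1, np.round(realization.syn_delay / dt)).astype(np.int32)
    if np.any(realization.syn_delay < dt):
        raise ConfigurationError("integration step exceeds the minimum delay")

    rate = realization.ext_rate_bc.copy()
    cfg = realization.config
    if r_ext_th is None:
        rate += realization.ext_rate_th
    else:
        rate += realization.ext_rate_th * (r_ext_th / cfg.r_ext_th)

    rm = realization.rm()
    stim_target = realization.stim_target if stimulus.segments else -1
    stim_mv = np.zeros(1)
    if stim_target >= 0:
        amps = stimulus.amplitude_steps(dt, n_pre, n_steps)
        stim_mv = rm[stim_target] * amps

    ref_steps = np.round(realization.tau_ref / dt).astype(np.int64)
    plast = _kernel.plasticity_vector(STRONG_DEPRESSION, WEAK_DEPRESSION,
                                      FACILITATING)

    # generous spike-buffer estimate from typical spontaneous rates
    T_sec = (t1 - t0) / 1000.0
    est = int(20.0 * realization.n_neurons * T_sec) + 20000
    while True:
        spk_neuron = np.empty(est, dtype=np.int32)
        spk_step = np.empty(est, dtype=np.int32)
        n = _kernel.run_trial(
            trial_seed, realization.tau_m, realization.v_T, ref_steps,
            realization.tau_a, realization.delta_a, rm,
            rate, realization.ext_jump, cfg.bias_mV,
            realization.indptr, realization.syn_tgt, realization.syn_w,
            dstep, realization.syn_class, plast, stim_target, stim_mv,
            n_steps, dt, 10.0, spk_neuron, spk_step)
        if n >= 0:
            break
        est *= 4
    return TrialRecord(
        neuron=spk_neuron[:n].copy(),
        time=t0 + (spk_step[:n] + 1.0) * dt,
        t_start=t0, t_end=t1, dt=dt, stimulus=stimulus, trial_seed=int(trial_seed),
        pop=realization.pop, stim_target=realization.stim_target,
        r_ext_th=r_ext_th)


def simulate_batch(realization: NetworkRealization,
                   stimulus=CATCH,
                   n_trials: int = 10,
                   master_seed: int = 0,
                   sim: SimConfig | None = None,
                   t_end: float | None = None,
                   sigma_r_ext: float = 0.0,
                   progress=None) -> list[TrialRecord]:
    """Simulate independent trials; shot noise and initial state fresh per trial.

    ``stimulus`` may be a fixed :class:`StimulusSpec` or a callable
    ``f(trial_index, rng) -> StimulusSpec`` (used for the per-trial irregular
    permutations).  ``sigma_r_ext`` > 0 additionally draws the thalamic
    background rate per trial from the fixed-mean lognormal.
    """
    from .stimuli import modulated_background

    seeds = _trial_seed_stream(master_seed, n_trials)
    aux = np.random.default_rng(np.random.SeedSequence(master_seed).spawn(1)[0])
    records = []
    for j in range(n_trials):
        spec = stimulus(j, aux) if callable(stimulus) else stimulus
        r_th = None
        if sigma_r_ext > 0:
            r_th = modulated_background(sigma_r_ext, aux,
                                        realization.config.r_ext_th)
        records.append(simulate_trial(realization, spec, int(seeds[j]), sim,
                                      t_end=t_end, r_ext_th=r_th))
        if progress is not None:
            progress(j + 1, n_trials)
    return records


@dataclass(frozen=True)
class EvokedStats:
    mean_count: float
    sd_count: float
    mean_rate: float   # Hz over the window
    mean_cv: float     # ISI CV averaged over trials with >= 3 spikes
    n_trials: int


def evoked_spike_stats(records: list[TrialRecord],
                       window: tuple[float, float] | None = None) -> EvokedStats:
    """Spike count / rate / ISI regularity of the stimulated cell in the window."""
    if len(records) < 2:
        raise ValueError("need at least two trials")
    if window is None:
        window = (0.0, records[0].stimulus.duration)
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty stimulation window")
    counts, cvs = [], []
    for rec in records:
        t = rec.spikes_of(rec.stim_target)
        t = t[(t >= lo) & (t < hi)]
        counts.append(t.size)
        if t.size >= 3:
            isi = np.diff(t)
            cvs.append(np.std(isi) / np.mean(isi))
    counts = np.asarray(counts, dtype=float)
    return EvokedStats(
        mean_count=float(np.mean(counts)),
        sd_count=float(np.std(counts)),
        mean_rate=float(np.mean(counts) / ((hi - lo) / 1000.0)),
        mean_cv=float(np.mean(cvs)) if cvs else np.nan,
        n_trials=len(records))


def exp_filter(x: np.ndarray, tau_ms: float, dt_ms: float) -> np.ndarray:
    """Causal convolution with the normalized kernel exp(-t/tau)/tau."""
    from scipy.signal import lfilter
    decay = np.exp(-dt_ms / tau_ms)
    # normalized so the discrete kernel has exactly unit sum (DC gain 1)
    return lfilter([1.0 - decay], [1.0, -decay], x, axis=-1)


def record_grid(rec: TrialRecord, record_dt: float = 1.0) -> np.ndarray:
    return np.arange(rec.t_start, rec.t_end + record_dt / 2, record_dt)


def binned_population_rate(rec: TrialRecord, pop_code: int,
                           record_dt: float = 1.0,
                           exclude: tuple = ()) -> np.ndarray:
    """Instantaneous population rate (Hz) on the recording grid, one trial."""
    n_pop = int(np.sum(rec.pop == pop_code)) - len(exclude)
    if n_pop <= 0:
        raise ValueError(f"unknown or empty population {pop_code!r}")
    mask = rec.population_mask(pop_code)
    if exclude:
        mask &= ~np.isin(rec.neuron, exclude)
    t = rec.time[mask]
    n_bins = int(round((rec.t_end - rec.t_start) / record_dt))
    idx = np.floor((t - rec.t_start) / record_dt).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return counts / n_pop / (record_dt / 1000.0)


def population_rate(records: list[TrialRecord], pop_code: int,
                    filter_tau: float = 15.0, record_dt: float = 1.0,
                    exclude: tuple = ()):
    """Trial-averaged, exponentially filtered population rate.

    Returns ``(t_grid, rate_hz)``; the grid gives left bin edges.
    """
    if not records:
        raise ValueError("need at least one trial")
    acc = None
    for rec in records:
        r = binned_population_rate(rec, pop_code, record_dt, exclude)
        acc = r if acc is None else acc + r
    mean = acc / len(records)
    t = np.arange(records[0].t_start, records[0].t_end, record_dt)
    return t[:mean.size], exp_filter(mean, filter_tau, record_dt)


def population_mean_rates(records: list[TrialRecord], pops=(0, 1, 2),
                          window: tuple[float, float] | None = None) -> dict:
    """Population-mean firing rates (Hz) from spike counts in a window."""
    out = {}
    for p in pops:
        n_pop = int(np.sum(records[0].pop == p))
        if n_pop == 0:
            raise ValueError(f"unknown or empty population {p!r}")
        total = 0.0
        T_total = 0.0
        for rec in records:
            lo = rec.t_start if window is None else window[0]
            hi = rec.t_end if window is None else window[1]
            m = rec.population_mask(p) & (rec.time >= lo) & (rec.time < hi)
            total += float(np.sum(m))
            T_total += (hi - lo) / 1000.0
        out[p] = total / n_pop / T_total
    return out
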