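"""Readout activities computed from recorded spike trains.

Three schemes observe the barrel-cortex network:

* integrator readout (IR): the filtered, signed, depression-weighted summed
  activity of fixed readout subsets of the RS/FS/SOM populations — the
  membrane potential of one grandmother cell without fire-and-reset,
* differentiator readout (DR): the running difference of the IR activity at
  a fixed lag, smoothed with a causal exponential kernel,
* differentiator network readout (DNR): the filtered mean firing rate of the
  excitatory readout population (SB) of an explicit excitatory-inhibitory
  circuit whose delayed feed-forward inhibition approximates the DR's
  subtraction (simulated together with the BCN; see
  :func:`nanostim.network.build_network` with ``with_dnr=True``).

The IR/DR computation is exact post-processing: the depressing readout
weights depend only on presynaptic spike trains, so their time course is
reconstructed spike-by-spike from the recorded trains with the same
master-variable rules used inside the network.
"""

from __future__ import annotations

import numpy as np

from .network import IRReadout, NetworkRealization
from .params import (FS, RS, SB, SOM, STRONG_DEPRESSION, WEAK_DEPRESSION,
                     ConfigurationError, ReadoutConfig)
from .plasticity import depression_factors
from .simulate import TrialRecord, exp_filter

_READOUT_SIGN = {RS: +1.0, FS: -1.0, SOM: -1.0}
_READOUT_PLAST = {RS: STRONG_DEPRESSION, FS: STRONG_DEPRESSION,
                  SOM: WEAK_DEPRESSION}


def trace_grid(rec: TrialRecord, record_dt: float = 1.0) -> np.ndarray:
    """Left edges of the recording bins of a trial."""
    n = int(round((rec.t_end - rec.t_start) / record_dt))
    return rec.t_start + np.arange(n) * record_dt


def ir_activity(rec: TrialRecord, ir: IRReadout,
                record_dt: float = 1.0) -> np.ndarray:
    """Integrator-readout activity A_ir(t) [mV] on the recording grid.

    Every spike of a readout-set neuron deflects the activity by its
    (depression-scaled) readout weight — positive for RS sources, negative
    for FS and SOM — and the activity relaxes back with the RS membrane
    time constant.
    """
    t_grid = trace_grid(rec, record_dt)
    n_bins = t_grid.size
    jumps = np.zeros(n_bins)
    order = np.lexsort((rec.time, rec.neuron))
    neu = rec.neuron[order]
    tim = rec.time[order]
    starts = np.searchsorted(neu, np.arange(rec.pop.size + 1))
    for pop_code, members in ir.members.items():
        sign = _READOUT_SIGN[pop_code]
        plast = _READOUT_PLAST[pop_code]
        weights = ir.weights[pop_code]
        for w, i in zip(weights, members):
            lo, hi = starts[i], starts[i + 1]
            if lo == hi:
                continue
            t = tim[lo:hi]
            f = depression_factors(t, plast)
            idx = np.minimum(((t - rec.t_start) / record_dt).astype(int),
                             n_bins - 1)
            np.add.at(jumps, idx, sign * w * f)
    decay = np.exp(-record_dt / ir.config.tau_ir)
    from scipy.signal import lfilter
    return lfilter([1.0], [1.0, -decay], jumps)


def dr_activity(ir_trace: np.ndarray, delta_T: float = 10.0,
                tau_filter: float = 15.0, record_dt: float = 1.0) -> np.ndarray:
    """Differentiator readout: lagged difference of A_ir, exponentially smoothed."""
    lag = int(round(delta_T / record_dt))
    diff = np.zeros_like(ir_trace)
    if lag > 0:
        diff[lag:] = ir_trace[lag:] - ir_trace[:-lag]
    return exp_filter(diff, tau_filter, record_dt)


def dnr_activity(rec: TrialRecord, realization: NetworkRealization,
                 tau_filter: float = 15.0, record_dt: float = 1.0) -> np.ndarray:
    """DNR activity: filtered mean SB-population firing rate [Hz]."""
    if not realization.has_dnr:
        raise ConfigurationError(
            "DNR trace requested but the realization carries no readout network")
    n_sb = int(np.sum(realization.pop == SB))
    mask = rec.population_mask(SB)
    t = rec.time[mask]
    n_bins = int(round((rec.t_end - rec.t_start) / record_dt))
    idx = np.clip(((t - rec.t_start) / record_dt).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    rate = counts / n_sb / (record_dt / 1000.0)
    return exp_filter(rate, tau_filter, record_dt)


def compute_traces(records: list[TrialRecord],
                   realization: NetworkRealization,
                   which=("ir", "dr", "dnr"),
                   ir: IRReadout | None = None,
                   readout: ReadoutConfig | None = None,
                   record_dt: float = 1.0):
    """Per-trial readout traces for a batch.

    Returns ``(t_grid, {name: array of shape (n_trials, n_bins)})``.  Passing
    an alternative ``ir`` membership allows readout-size sweeps without
    re-simulating the network.
    """
    rcfg = readout or realization.readout_config
    ir = ir or realization.ir
    t_grid = trace_grid(records[0], record_dt)
    out = {}
    need_ir = "ir" in which or "dr" in which
    if need_ir:
        airs = np.stack([ir_activity(r, ir, record_dt) for r in records])
        if "ir" in which:
            out["ir"] = airs
        if "dr" in which:
            out["dr"] = np.stack([
                dr_activity(a, rcfg.delta_T, rcfg.tau_filter, record_dt)
                for a in airs])
    if "dnr" in which:
        out["dnr"] = np.stack([
            dnr_activity(r, realization, rcfg.tau_filter, record_dt)
            for r in records])
    return t_grid, out
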