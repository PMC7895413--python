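"""End-to-end experiment protocols: build, simulate, read out, detect.

Each experiment mirrors one stimulation protocol: the duration series
(100/200/400 ms steps at 25% intensity), the charge-matched intensity series,
the regular-vs-irregular comparison, readout-size and lag sweeps, and the
background-noise robustness sweep.  Every experiment simulates two
equally-sized catch-trial sets (the second estimates the size of random
fluctuations via the catch-vs-catch "effect size") plus the stimulus
conditions, computes the requested readout traces, calibrated effect sizes
and standardized statistics, and returns (and optionally writes) tidy tables
with full seed provenance.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detection import (BOUNDARY_BY_READOUT, DetectionResult, effect_size,
                        standardized_stats)
from .network import build_ir_readout, build_network
from .params import FS, RS, SOM, Preset, load_preset
from .readouts import compute_traces
from .simulate import simulate_batch
from .stimuli import CATCH, irregular_stimulus, step_stimulus

EXPERIMENTS = ("duration", "intensity", "regularity", "readout_size_sweep",
               "deltaT_sweep", "background_noise")


@dataclass
class ExperimentPlan:
    experiment: str
    preset: str | Preset = "desk_small"
    n_trials: int = 200
    readouts: tuple = ("ir", "dr", "dnr")
    master_seed: int = 0
    out_dir: str | None = None
    t_end: float = 700.0          # ms; detection uses (0, 600 ms)
    sweep_values: tuple | None = None

    def resolve_preset(self) -> Preset:
        return self.preset if isinstance(self.preset, Preset) \
            else load_preset(self.preset)


def _condition_stimuli(experiment: str):
    if experiment == "duration":
        return {f"step{d}_25": step_stimulus(d, 0.25) for d in (100, 200, 400)}
    if experiment == "intensity":
        return {"step100_100": step_stimulus(100, 1.0),
                "step200_50": step_stimulus(200, 0.5),
                "step400_25": step_stimulus(400, 0.25)}
    if experiment == "regularity":
        # two independent irregular-stimulus samples, as in the published
        # protocol, to expose finite-size fluctuations over the 720 signals
        return {"step400_25": step_stimulus(400, 0.25),
                "irregular_a": (lambda j, rng: irregular_stimulus(rng)),
                "irregular_b": (lambda j, rng: irregular_stimulus(rng))}
    raise ValueError(f"unknown experiment {experiment!r}")


@dataclass
class ExperimentResult:
    plan: ExperimentPlan
    detection: pd.DataFrame       # one row per condition x readout
    stats: dict                   # condition -> readout -> StandardizedStats
    traces: dict                  # condition -> (t_grid, {readout: 2D array})
    manifest: dict


def run_experiment(plan: ExperimentPlan) -> ExperimentResult:
    """Execute one named protocol end-to-end; reproducible from the plan."""
    if plan.experiment in ("readout_size_sweep", "deltaT_sweep",
                           "background_noise"):
        param = {"readout_size_sweep": "N_read_RS",
                 "deltaT_sweep": "delta_T",
                 "background_noise": "sigma_r_ext"}[plan.experiment]
        raise ValueError(
            f"{plan.experiment} is a sweep; call sweep(plan, {param!r}, values)")
    preset = plan.resolve_preset()
    t_wall = time.time()
    with_dnr = "dnr" in plan.readouts
    net = build_network(preset.network, seed=plan.master_seed,
                        readout_config=preset.readout, with_dnr=with_dnr)
    conditions = {"catch_b": CATCH, **_condition_stimuli(plan.experiment)}
    sigma = 0.0
    batches, traces = {}, {}
    base_kwargs = dict(sim=preset.sim, t_end=plan.t_end)

    seeds = {name: plan.master_seed * 1000 + j
             for j, name in enumerate(["catch_a", *conditions])}
    batches["catch_a"] = simulate_batch(net, CATCH, plan.n_trials,
                                        seeds["catch_a"], **base_kwargs)
    for name, stim in conditions.items():
        batches[name] = simulate_batch(net, stim, plan.n_trials,
                                       seeds[name], sigma_r_ext=sigma,
                                       **base_kwargs)
    for name, recs in batches.items():
        traces[name] = compute_traces(recs, net, which=plan.readouts)

    rows, stats = [], {}
    t_grid, catch_tr = traces["catch_a"]
    for name in conditions:
        _, cond_tr = traces[name]
        stats[name] = {}
        for ro in plan.readouts:
            res = effect_size(cond_tr[ro], catch_tr[ro], t_grid,
                              BOUNDARY_BY_READOUT[ro], readout=ro,
                              seed=plan.master_seed + 17)
            rows.append(_detection_row(plan, name, res, seeds))
            stats[name][ro] = standardized_stats(cond_tr[ro], catch_tr[ro],
                                                 t_grid)
    detection = pd.DataFrame(rows)
    manifest = {
        "experiment": plan.experiment, "preset": preset.name,
        "n_trials": plan.n_trials, "master_seed": plan.master_seed,
        "condition_seeds": seeds, "version": __version__,
        "wall_time_s": round(time.time() - t_wall, 2),
    }
    result = ExperimentResult(plan, detection, stats, traces, manifest)
    if plan.out_dir:
        _write_result(result)
    return result


def _detection_row(plan, condition, res: DetectionResult, seeds) -> dict:
    return {
        "experiment": plan.experiment, "condition": condition,
        "readout": res.readout, "boundary": res.boundary,
        "threshold": res.threshold, "fp": res.fp, "cd": res.cd,
        "effect_size": res.effect_size, "ci_halfwidth": res.ci_halfwidth,
        "n_stim": res.n_stim, "n_catch": res.n_catch,
        "master_seed": plan.master_seed, "condition_seed": seeds[condition],
        "version": __version__,
    }


def _write_result(result: ExperimentResult) -> None:
    out = Path(result.plan.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.detection.to_csv(out / "detection.csv", index=False)
    for cond, per_ro in result.stats.items():
        for ro, st in per_ro.items():
            df = pd.DataFrame({"t_ms": st.t_grid, "mu_hat": st.mu_hat,
                               "sigma_hat": st.sigma_hat})
            df.to_csv(out / f"stats_{cond}_{ro}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def readout_size_sweep(plan: ExperimentPlan, parameter: str,
                       values) -> pd.DataFrame:
    """Effect size vs readout-set size, recomputed from one simulated batch.

    The integrator readout is pure post-processing of the recorded spikes,
    so membership of different sizes can be re-drawn and re-evaluated without
    re-simulating the network.  ``parameter`` is one of ``N_read_RS``,
    ``N_read_FS``, ``N_read_SOM``.
    """
    preset = plan.resolve_preset()
    net = build_network(preset.network, seed=plan.master_seed,
                        readout_config=preset.readout, with_dnr=False)
    conditions = {"step400_25": step_stimulus(400, 0.25),
                  "irregular": (lambda j, rng: irregular_stimulus(rng))}
    batches = {"catch": simulate_batch(net, CATCH, plan.n_trials,
                                       plan.master_seed * 1000,
                                       sim=preset.sim, t_end=plan.t_end)}
    for j, (name, stim) in enumerate(conditions.items()):
        batches[name] = simulate_batch(net, stim, plan.n_trials,
                                       plan.master_seed * 1000 + j + 1,
                                       sim=preset.sim, t_end=plan.t_end)
    rows = []
    rng = np.random.default_rng(plan.master_seed + 99)
    for v in values:
        rcfg = dataclasses.replace(preset.readout, **{parameter: int(v)})
        ir = build_ir_readout(net.pop, rcfg, rng, preset.network)
        t_grid, catch_tr = compute_traces(batches["catch"], net,
                                          which=("ir", "dr"), ir=ir,
                                          readout=rcfg)
        for name in conditions:
            _, cond_tr = compute_traces(batches[name], net,
                                        which=("ir", "dr"), ir=ir,
                                        readout=rcfg)
            for ro in ("ir", "dr"):
                if ro not in plan.readouts:
                    continue
                res = effect_size(cond_tr[ro], catch_tr[ro], t_grid,
                                  BOUNDARY_BY_READOUT[ro], readout=ro,
                                  seed=plan.master_seed + 17)
                rows.append({"parameter": parameter, "value": v,
                             "condition": name, "readout": ro,
                             "effect_size": res.effect_size,
                             "ci_halfwidth": res.ci_halfwidth,
                             "fp": res.fp, "cd": res.cd,
                             "master_seed": plan.master_seed})
    return pd.DataFrame(rows)


def delta_T_sweep(plan: ExperimentPlan, values) -> pd.DataFrame:
    """DR effect size vs differentiator lag, from one simulated batch."""
    preset = plan.resolve_preset()
    net = build_network(preset.network, seed=plan.master_seed,
                        readout_config=preset.readout, with_dnr=False)
    conditions = {"step400_25": step_stimulus(400, 0.25),
                  "irregular": (lambda j, rng: irregular_stimulus(rng))}
    batches = {"catch": simulate_batch(net, CATCH, plan.n_trials,
                                       plan.master_seed * 1000,
                                       sim=preset.sim, t_end=plan.t_end)}
    for j, (name, stim) in enumerate(conditions.items()):
        batches[name] = simulate_batch(net, stim, plan.n_trials,
                                       plan.master_seed * 1000 + j + 1,
                                       sim=preset.sim, t_end=plan.t_end)
    rows = []
    for v in values:
        rcfg = dataclasses.replace(preset.readout, delta_T=float(v))
        t_grid, catch_tr = compute_traces(batches["catch"], net,
                                          which=("dr",), readout=rcfg)
        for name in conditions:
            _, cond_tr = compute_traces(batches[name], net, which=("dr",),
                                        readout=rcfg)
            res = effect_size(cond_tr["dr"], catch_tr["dr"], t_grid,
                              BOUNDARY_BY_READOUT["dr"], readout="dr",
                              seed=plan.master_seed + 17)
            rows.append({"parameter": "delta_T", "value": v,
                         "condition": name, "readout": "dr",
                         "effect_size": res.effect_size,
                         "ci_halfwidth": res.ci_halfwidth,
                         "master_seed": plan.master_seed})
    return pd.DataFrame(rows)


def background_noise_sweep(plan: ExperimentPlan, sigma_values) -> pd.DataFrame:
    """Effect size vs static background-rate modulation (slow nonstationarity)."""
    preset = plan.resolve_preset()
    with_dnr = "dnr" in plan.readouts
    net = build_network(preset.network, seed=plan.master_seed,
                        readout_config=preset.readout, with_dnr=with_dnr)
    rows = []
    for si, sigma in enumerate(sigma_values):
        batches = {
            "catch": simulate_batch(net, CATCH, plan.n_trials,
                                    plan.master_seed * 1000 + 100 * si,
                                    sim=preset.sim, t_end=plan.t_end,
                                    sigma_r_ext=sigma),
            "step400_25": simulate_batch(net, step_stimulus(400, 0.25),
                                         plan.n_trials,
                                         plan.master_seed * 1000 + 100 * si + 1,
                                         sim=preset.sim, t_end=plan.t_end,
                                         sigma_r_ext=sigma),
            "irregular": simulate_batch(net, lambda j, rng: irregular_stimulus(rng),
                                        plan.n_trials,
                                        plan.master_seed * 1000 + 100 * si + 2,
                                        sim=preset.sim, t_end=plan.t_end,
                                        sigma_r_ext=sigma),
        }
        t_grid, catch_tr = compute_traces(batches["catch"], net,
                                          which=plan.readouts)
        for name in ("step400_25", "irregular"):
            _, cond_tr = compute_traces(batches[name], net, which=plan.readouts)
            for ro in plan.readouts:
                res = effect_size(cond_tr[ro], catch_tr[ro], t_grid,
                                  BOUNDARY_BY_READOUT[ro], readout=ro,
                                  seed=plan.master_seed + 17)
                rows.append({"parameter": "sigma_r_ext", "value": sigma,
                             "condition": name, "readout": ro,
                             "effect_size": res.effect_size,
                             "ci_halfwidth": res.ci_halfwidth,
                             "master_seed": plan.master_seed})
    return pd.DataFrame(rows)


def sweep(plan: ExperimentPlan, parameter: str, values) -> pd.DataFrame:
    """Dispatch a one-parameter sweep (readout sizes, lag, background noise)."""
    if parameter in ("N_read_RS", "N_read_FS", "N_read_SOM"):
        return readout_size_sweep(plan, parameter, values)
    if parameter in ("delta_T", "deltaT"):
        return delta_T_sweep(plan, values)
    if parameter == "sigma_r_ext":
        return background_noise_sweep(plan, values)
    raise ValueError(f"unknown sweep parameter {parameter!r}")
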