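"""Detection statistics: threshold calibration, effect sizes, standardized
trace statistics, and the simplified independent-draw detection model.

A trial is a "detection" when its readout trace crosses a decision boundary
at least once inside the detection window (0, T_w): a *lower* boundary for
the integrator readout, an *upper* boundary for the two differentiators.
The boundary is calibrated on catch trials so that the false-positive rate
is 0.25 (the experimentally observed average), and the reported effect size
is hit rate minus false-positive rate at that boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterError

LOWER, UPPER = "lower", "upper"
BOUNDARY_BY_READOUT = {"ir": LOWER, "dr": UPPER, "dnr": UPPER}


def _window_mask(t_grid: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return (t_grid > lo) & (t_grid < hi)


def trial_extrema(traces: np.ndarray, t_grid: np.ndarray, boundary: str,
                  window=(0.0, 600.0)) -> np.ndarray:
    """Per-trial extremum relevant for the boundary type inside the open window."""
    m = _window_mask(t_grid, window)
    if not np.any(m):
        raise ParameterError("empty detection window")
    sub = traces[:, m]
    return sub.min(axis=1) if boundary == LOWER else sub.max(axis=1)


def detect(trace: np.ndarray, t_grid: np.ndarray, threshold: float,
           boundary: str, window=(0.0, 600.0)) -> bool:
    """True iff the trace crosses the boundary at any grid point in the window."""
    ext = trial_extrema(trace[None, :], t_grid, boundary, window)[0]
    return bool(ext < threshold) if boundary == LOWER else bool(ext > threshold)


def crossing_fraction(traces, t_grid, threshold, boundary, window=(0.0, 600.0)):
    ext = trial_extrema(traces, t_grid, boundary, window)
    return float(np.mean(ext < threshold if boundary == LOWER
                         else ext > threshold))


def calibrate_threshold(catch_traces: np.ndarray, t_grid: np.ndarray,
                        boundary: str, target_fp: float = 0.25,
                        window=(0.0, 600.0)) -> float:
    """Boundary value at which the catch-trial crossing fraction equals target_fp.

    The crossing indicator is monotone in the threshold, so the calibrated
    boundary is the corresponding quantile of the per-trial extrema.
    """
    if not 0.0 <= target_fp <= 1.0:
        raise ParameterError("target false-positive rate must be in [0, 1]")
    ext = trial_extrema(catch_traces, t_grid, boundary, window)
    if boundary == LOWER:
        # FP = P(min < theta): theta at the target_fp quantile of minima
        return float(np.quantile(ext, target_fp))
    return float(np.quantile(ext, 1.0 - target_fp))


@dataclass(frozen=True)
class DetectionResult:
    readout: str
    boundary: str
    threshold: float
    fp: float               # false-positive rate on held-out catch trials
    cd: float               # correct-detection (hit) rate on stimulus trials
    effect_size: float      # cd - fp
    ci_halfwidth: float     # bootstrap CI half-width of the effect size
    n_stim: int
    n_catch: int


def effect_size(stim_traces: np.ndarray, catch_traces: np.ndarray,
                t_grid: np.ndarray, boundary: str, readout: str = "",
                target_fp: float = 0.25, window=(0.0, 600.0),
                n_boot: int = 1000, seed: int = 0) -> DetectionResult:
    """Calibrated effect size with a bootstrap confidence interval.

    The boundary is calibrated on one half of the catch trials; the
    false-positive rate entering the effect size is evaluated on the held-out
    half to avoid optimistic bias.  The bootstrap resamples trials within
    each set.
    """
    n_catch = catch_traces.shape[0]
    half = n_catch // 2
    calib, holdout = catch_traces[:half], catch_traces[half:]
    theta = calibrate_threshold(calib, t_grid, boundary, target_fp, window)
    ext_hold = trial_extrema(holdout, t_grid, boundary, window)
    ext_stim = trial_extrema(stim_traces, t_grid, boundary, window)

    def rates(eh, es):
        if boundary == LOWER:
            return float(np.mean(eh < theta)), float(np.mean(es < theta))
        return float(np.mean(eh > theta)), float(np.mean(es > theta))

    fp, cd = rates(ext_hold, ext_stim)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        eh = rng.choice(ext_hold, ext_hold.size, replace=True)
        es = rng.choice(ext_stim, ext_stim.size, replace=True)
        f, c = rates(eh, es)
        boots[b] = c - f
    lo, hi = np.quantile(boots, [0.16, 0.84])
    return DetectionResult(readout=readout, boundary=boundary,
                           threshold=theta, fp=fp, cd=cd,
                           effect_size=cd - fp,
                           ci_halfwidth=float((hi - lo) / 2),
                           n_stim=stim_traces.shape[0], n_catch=n_catch)


@dataclass(frozen=True)
class StandardizedStats:
    t_grid: np.ndarray
    mu_hat: np.ndarray      # standardized trial-mean deviation
    sigma_hat: np.ndarray   # standardized trial-SD deviation
    mu_catch: float
    sigma_catch: float


def standardized_stats(stim_traces: np.ndarray, catch_traces: np.ndarray,
                       t_grid: np.ndarray,
                       baseline_window=(0.0, 600.0)) -> StandardizedStats:
    """Time-dependent trial statistics in units of the spontaneous SD.

    The spontaneous baseline mean and SD come from the catch ensemble (the
    spontaneous state is stationary, so time points inside the baseline
    window are pooled); the SD is the square root of the trial variance.
    """
    m = _window_mask(t_grid, baseline_window)
    mu_catch = float(np.mean(catch_traces[:, m]))
    sigma_catch = float(np.sqrt(np.mean(
        np.var(catch_traces[:, m], axis=0, ddof=1))))
    mu_hat = (stim_traces.mean(axis=0) - mu_catch) / sigma_catch
    sigma_hat = (stim_traces.std(axis=0, ddof=1) - sigma_catch) / sigma_catch
    return StandardizedStats(t_grid=t_grid, mu_hat=mu_hat,
                             sigma_hat=sigma_hat, mu_catch=mu_catch,
                             sigma_catch=sigma_catch)


def simplified_effect_size(p0: float, delta_p, n: int):
    """Effect size of the independent-draw detection model.

    The detection window is treated as ``n`` independent draws with baseline
    non-crossing probability ``p0``; each entry of ``delta_p`` perturbs one
    draw to ``p_i = p0 + delta_p_i``.  Returns ``(exact, additive)`` where
    the exact value is p0^n (1 - prod_i p_i/p0) and the additive value is the
    sum of the single-feature effect sizes p0^n (1 - p_i/p0).
    """
    delta_p = np.atleast_1d(np.asarray(delta_p, dtype=float))
    p = p0 + delta_p
    if not 0.0 < p0 <= 1.0 or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ParameterError("probabilities must lie in (0, 1]")
    if delta_p.size > n:
        raise ParameterError("more perturbed draws than draws in the window")
    exact = p0**n * (1.0 - np.prod(p / p0))
    additive = float(np.sum(p0**n * (1.0 - p / p0)))
    return float(exact), additive


def false_positive_rate_simplified(p0: float, n: int) -> float:
    """FP = 1 - p0^n for the independent-draw model."""
    return 1.0 - p0**n
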