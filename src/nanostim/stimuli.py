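"""Injected-current waveforms for the single-cell stimulation protocols.

A stimulus is a list of piecewise-constant segments starting at t = 0, with
amplitudes expressed as fractions of the maximum current (5 nA by default);
conversion to nA happens once at simulation time.  Catch trials carry an
empty segment list.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .params import ParameterError

# the six fixed steps shuffled to build an irregular stimulus:
# (duration ms, amplitude fraction); one step is hyperpolarizing.
IRREGULAR_STEPS = (
    (10.0, 1.0),
    (20.0, 0.5),
    (40.0, 0.25),
    (80.0, 0.125),
    (160.0, 0.0625),
    (90.0, -0.5),
)


@dataclass(frozen=True)
class StimulusSpec:
    """Piecewise-constant injected current, onset at t = 0."""
    segments: tuple = ()          # ((duration_ms, amplitude_frac), ...)
    tag: str = "catch"            # regular | charge_matched | irregular | catch
    I_max: float = 5.0            # nA
    permutation: tuple | None = None  # step order (irregular only)

    @property
    def duration(self) -> float:
        return float(sum(d for d, _ in self.segments))

    @property
    def charge_nC(self) -> float:
        """Injected charge in nC (duration in ms, current in nA)."""
        return sum(d * a for d, a in self.segments) * self.I_max / 1000.0

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        """Current in nA sampled at the given times."""
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        edges = np.concatenate([[0.0], np.cumsum([d for d, _ in self.segments])])
        for (dur, amp), lo, hi in zip(self.segments, edges[:-1], edges[1:]):
            out[(t >= lo) & (t < hi)] = amp * self.I_max
        return out

    def amplitude_steps(self, dt: float, n_pre: int, n_total: int) -> np.ndarray:
        """Current (nA) on the integration grid of a trial.

        ``n_pre`` steps precede the onset, ``n_total`` is the full trial length.
        """
        out = np.zeros(n_total)
        t = (np.arange(n_total) - n_pre) * dt
        out[:] = self.waveform(t)
        return out

    def export(self, path: str, dt: float = 1.0, t_max: float | None = None):
        """Two-column text export (t_ms, I_nA) for plotting and diffing."""
        t_max = self.duration if t_max is None else t_max
        t = np.arange(0.0, t_max + dt / 2, dt)
        np.savetxt(path, np.column_stack([t, self.waveform(t)]),
                   header="t_ms I_nA", fmt="%.6g")


CATCH = StimulusSpec()


def step_stimulus(duration: float, amplitude_frac: float,
                  I_max: float = 5.0) -> StimulusSpec:
    """Single rectangular step of the given length and relative intensity."""
    if duration <= 0:
        raise ParameterError("stimulus duration must be positive")
    return StimulusSpec(((float(duration), float(amplitude_frac)),),
                        tag="regular", I_max=I_max)


def charge_matched_set(I_max: float = 5.0):
    """The three constant-charge steps: (100 ms, 100%), (200, 50%), (400, 25%)."""
    specs = []
    for dur, amp in ((100.0, 1.0), (200.0, 0.5), (400.0, 0.25)):
        specs.append(StimulusSpec(((dur, amp),), tag="charge_matched", I_max=I_max))
    return tuple(specs)


def irregular_stimulus(rng_or_seed, I_max: float = 5.0) -> StimulusSpec:
    """One uniformly random permutation of the six fixed steps (400 ms total).

    Stimuli are drawn fresh in every trial; 6! = 720 distinct signals exist.
    """
    rng = np.random.default_rng(rng_or_seed) \
        if not isinstance(rng_or_seed, np.random.Generator) else rng_or_seed
    order = tuple(int(i) for i in rng.permutation(len(IRREGULAR_STEPS)))
    segs = tuple(IRREGULAR_STEPS[i] for i in order)
    return StimulusSpec(segs, tag="irregular", I_max=I_max, permutation=order)


def all_irregular_permutations(I_max: float = 5.0):
    """All 720 irregular signals (for exact ensemble averages)."""
    out = []
    for order in itertools.permutations(range(len(IRREGULAR_STEPS))):
        segs = tuple(IRREGULAR_STEPS[i] for i in order)
        out.append(StimulusSpec(segs, tag="irregular", I_max=I_max,
                                permutation=order))
    return out


def modulated_background(sigma_r_ext: float, rng_or_seed,
                         mean: float = 10.0) -> float:
    """Per-trial thalamic background rate under slow-nonstationarity proxy.

    One lognormal draw per trial with fixed arithmetic mean (10 Hz) and
    standard deviation ``sigma_r_ext``; sigma 0 returns the mean exactly.
    """
    if sigma_r_ext < 0:
        raise ParameterError("sigma_r_ext must be non-negative")
    if sigma_r_ext == 0:
        return float(mean)
    rng = np.random.default_rng(rng_or_seed) \
        if not isinstance(rng_or_seed, np.random.Generator) else rng_or_seed
    sigma2 = np.log1p((sigma_r_ext / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))
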