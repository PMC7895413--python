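"""Shot-noise firing-rate theory and the differentiator-network tuning.

The stationary firing rate of a leaky integrate-and-fire neuron driven by
white shot noise — Poisson streams of excitatory/inhibitory pulses with
exponentially distributed amplitudes ``a_e``/``a_i`` (mV) at rates
``R_e``/``R_i`` (Hz) plus a constant input ``mu0`` (mV) — has the closed form

    rate = 1 / ( tau_ref + tau_m * I ),
    I = ∫_0^{1/a_e} ds/s * Z0inv(s) * [ exp(s*vT') / (1 - a_e*s)
                                        - exp(s*vR') ],
    Z0inv(s) = (1 - a_e*s)^(tau_m*R_e) * (1 + a_i*s)^(tau_m*R_i),

with thresholds shifted by the constant input, ``vT' = v_T - mu0`` and
``vR' = v_R - mu0`` (times in seconds inside the exponents).  The derivative
of this rate with respect to ``mu0`` is the DC susceptibility used in the
linear-response tuning of the differentiator readout network: the mean I→SB
weight is chosen such that a static rate perturbation of the input network
arriving through the direct excitatory pathway is cancelled by the delayed
disynaptic inhibitory pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .params import (FS_PARAMS, RS_PARAMS, STRONG_DEPRESSION, NetworkConfig,
                     ParameterError, ReadoutConfig)
from .plasticity import mean_depression_factor


class NumericalError(RuntimeError):
    pass


def shot_noise_rate(a_e: float, a_i: float, R_e: float, R_i: float,
                    mu0: float, tau_m: float, tau_ref: float,
                    v_T: float = 20.0, v_R: float = 10.0) -> float:
    """Stationary rate [Hz] of a shot-noise-driven LIF neuron.

    ``a_e``/``a_i`` in mV, ``R_e``/``R_i`` in Hz, ``mu0`` = R_m I_0 in mV,
    ``tau_m``/``tau_ref`` in ms.
    """
    if a_e <= 0:
        raise ParameterError("excitatory jump amplitude must be positive")
    if R_e < 0 or R_i < 0:
        raise ParameterError("input rates must be non-negative")
    tau_s = tau_m / 1000.0        # s
    vT = v_T - mu0
    vR = v_R - mu0
    ce = tau_s * R_e              # dimensionless exponents
    ci = tau_s * R_i
    if R_e == 0.0 and vT > 0:
        return 0.0                # no upward jumps, subthreshold mean drive

    def integrand(s):
        if s <= 0.0:
            return vT + a_e - vR  # continuous limit at s -> 0
        le = np.log1p(-a_e * s)
        li = np.log1p(a_i * s) if a_i > 0 else 0.0
        base = ce * le + ci * li - np.log(s)
        return np.exp(base + s * vT - le) - np.exp(base + s * vR)

    upper = 1.0 / a_e
    val, err = quad(integrand, 0.0, upper, limit=400,
                    points=[upper * f for f in (0.5, 0.9, 0.99)])
    if not np.isfinite(val) or (abs(val) > 1e-8 and err > 1e-4 * abs(val)):
        raise NumericalError(
            f"shot-noise quadrature did not converge (value={val}, err={err})")
    denom = tau_ref / 1000.0 + tau_s * val
    return 1.0 / denom


def dc_susceptibility(a_e, a_i, R_e, R_i, mu0, tau_m, tau_ref,
                      v_T=20.0, v_R=10.0, h: float = 0.05) -> float:
    """d(rate)/d(mu0) [Hz/mV] by central finite difference of the rate formula."""
    up = shot_noise_rate(a_e, a_i, R_e, R_i, mu0 + h, tau_m, tau_ref, v_T, v_R)
    dn = shot_noise_rate(a_e, a_i, R_e, R_i, mu0 - h, tau_m, tau_ref, v_T, v_R)
    return (up - dn) / (2.0 * h)


def lif_deterministic_rate(mu: float, tau_m: float, tau_ref: float,
                           v_T: float = 20.0, v_R: float = 10.0) -> float:
    """Textbook noiseless LIF rate [Hz] for constant suprathreshold drive mu [mV]."""
    if mu <= v_T:
        return 0.0
    T = tau_ref + tau_m * np.log((mu - v_R) / (mu - v_T))
    return 1000.0 / T


def j_ei_r_formula(J_ee_FF: float, J_ie_FF: float, J_ii_R: float,
                   C_ei_R: int, C_ii_R: int, phi_prime: float,
                   Rbar_I: float, tau_m_i: float) -> float:
    """Cancellation weight [mV] given the inhibitory operating point.

    Linear-response balance of the direct excitatory and disynaptic
    inhibitory feed-forward pathways; ``phi_prime`` is the DC susceptibility
    [Hz/mV] of the inhibitory readout population and ``Rbar_I`` its mean
    depression factor.  Homogeneous of degree one in ``J_ee_FF``.
    """
    tau_s = tau_m_i / 1000.0
    return (J_ee_FF * (1.0 + tau_s * phi_prime * J_ii_R * Rbar_I * C_ii_R)
            / (tau_s * phi_prime * J_ie_FF * C_ei_R * Rbar_I))


@dataclass(frozen=True)
class TuningResult:
    J_ei_R: float        # mV, weight satisfying the cancellation condition
    r_I: float           # Hz, self-consistent rate of the inhibitory readout
    susceptibility: float  # Hz/mV at the operating point
    r_tot_in: float      # Hz, total excitatory input rate entering the fixpoint
    residual: float      # relative self-consistency residual at r_I


def tune_J_ei_R(r_e: float = 0.8,
                network: NetworkConfig | None = None,
                readout: ReadoutConfig | None = None) -> TuningResult:
    """Linear-response tuning of the inhibitory readout weight.

    Imposes that a static shift in the mean input to the excitatory readout
    population via the direct pathway is cancelled by the (delayed)
    feed-forward inhibitory pathway, and solves for the mean I→SB weight.
    The inhibitory readout population's spontaneous rate ``r_I`` comes from
    the shot-noise self-consistency condition; the DC susceptibility enters
    through the linear response of ``r_I`` to input perturbations.
    """
    cfg = network or NetworkConfig()
    rcfg = readout or ReadoutConfig()
    J_ee_FF = cfg.connections[(0, 0)].J_mean          # BCN RS -> SB, 0.1 mV
    J_ie_FF = cfg.connections[(1, 0)].J_mean          # BCN RS -> I, 0.2 mV
    J_ii_R = cfg.connections[(1, 1)].J_mean           # I -> I, 1.0 mV
    C_ei_R = rcfg.C_ii_R                              # I -> SB fan-in, 200
    C_ii_R = rcfg.C_ii_R                              # I -> I fan-in, 200
    C_hat = rcfg.N_read_RS                            # BCN RS fan-in, 1000

    # total excitatory input rate to the inhibitory readout population:
    # feed-forward BCN spikes plus the readout's external background (the
    # cortical-surround stream runs at half the in-network rate).
    fp = FS_PARAMS
    rp = RS_PARAMS
    r_tot_in = (C_hat * r_e
                + rp.C_ext_bc * cfg.r_ext_bc * rcfg.bc_rate_factor
                + rp.C_ext_th * cfg.r_ext_th)
    tau_m_i = fp.tau_m_mean
    tau_ref_i = fp.tau_ref0 + fp.tau_ref_extra_mean
    mu0 = cfg.bias_mV

    def excess(r):
        return shot_noise_rate(J_ee_FF, J_ii_R, r_tot_in, C_ii_R * r, mu0,
                               tau_m_i, tau_ref_i) - r

    r_max = 1000.0 / tau_ref_i - 1e-6
    lo, hi = 1e-6, r_max
    if excess(lo) < 0 or excess(hi) > 0:
        raise NumericalError("no self-consistent inhibitory readout rate "
                             "in (0, 1/tau_ref)")
    r_I = brentq(excess, lo, hi, xtol=1e-10, rtol=1e-14)
    residual = abs(excess(r_I)) / max(r_I, 1e-12)

    phi_p = dc_susceptibility(J_ee_FF, J_ii_R, r_tot_in, C_ii_R * r_I, mu0,
                              tau_m_i, tau_ref_i)
    Rbar_I = float(mean_depression_factor(r_I, STRONG_DEPRESSION.tau_D,
                                          STRONG_DEPRESSION.U_se))
    J = j_ei_r_formula(J_ee_FF, J_ie_FF, J_ii_R, C_ei_R, C_ii_R, phi_p,
                       Rbar_I, tau_m_i)
    return TuningResult(J_ei_R=float(J), r_I=float(r_I),
                        susceptibility=float(phi_p),
                        r_tot_in=float(r_tot_in), residual=float(residual))
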