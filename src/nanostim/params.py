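"""Model parameters of the barrel-cortex network (BCN) and its readouts.

The network describes the ~200 um surroundings of a stimulated cell in the rat
barrel cortex: 2000 excitatory regular-spiking (RS) neurons, 400 fast-spiking
(FS) interneurons and 200 somatostatin-positive low-threshold-spiking (SOM-LTS)
interneurons, all leaky integrate-and-fire units with heterogeneous cellular
parameters.  This module collects every numeric constant of the model, the
random-sampling conventions for the heterogeneous parameters, and the two
shipped presets (``published_default`` and ``desk_small``).

Units: time in ms, voltages/PSP amplitudes in mV, currents in nA, rates in Hz.
The membrane capacitance ``C_M`` = 150 pF is shared by all neurons, so the
membrane resistance of neuron *k* is ``tau_m_k / C_M`` in mV/nA.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

# population codes used throughout the package
RS, FS, SOM, SB, INH_READ = 0, 1, 2, 3, 4
POP_NAMES = {RS: "RS", FS: "FS", SOM: "SOM", SB: "SB", INH_READ: "I"}

# synapse plasticity classes
STATIC, STRONG, WEAK, FACIL = 0, 1, 2, 3

C_M = 150.0e-3  # nA*ms/mV  (150 pF); R_m = tau_m / C_m in mV/nA


class ParameterError(ValueError):
    """Raised for invalid model-parameter values."""


class ConfigurationError(ValueError):
    """Raised for inconsistent network configurations (e.g. fan-in > pool)."""


def sample_lognormal(mean: float, rel_sd: float, n: int, rng: np.random.Generator):
    """Sample a lognormal with given *arithmetic* mean and relative SD.

    The quoted physiological values (e.g. mean membrane time constant 20 ms,
    SD 20% of the mean) are interpreted as moments of the lognormal itself,
    not of the underlying normal; hence sigma^2 = ln(1 + rel_sd^2) and
    mu = ln(mean) - sigma^2/2.  ``rel_sd=0`` degenerates to a constant.
    """
    if mean <= 0:
        raise ParameterError(f"lognormal mean must be positive, got {mean}")
    if rel_sd < 0:
        raise ParameterError(f"relative SD must be non-negative, got {rel_sd}")
    if rel_sd == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p(rel_sd**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def sample_thresholds(mean: float, rel_sd: float, v_reset: float, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian firing thresholds, redrawn (not truncated) until v_T > v_R."""
    v = rng.normal(mean, rel_sd * mean, size=n)
    bad = v <= v_reset
    while np.any(bad):
        v[bad] = rng.normal(mean, rel_sd * mean, size=int(bad.sum()))
        bad = v <= v_reset
    return v


@dataclass(frozen=True)
class PlasticityParams:
    """Short-term plasticity parameters of one synapse class.

    ``mode`` is one of the class codes STATIC/STRONG/WEAK/FACIL.  Depressing
    synapses follow the Tsodyks-Markram resource variable with recovery time
    ``tau_D`` and release probability ``U_se``.  The facilitating RS→SOM class
    additionally carries a facilitation variable (baseline ``U_b``, jump ``U``,
    recovery ``tau_F``) and an activity-dependent transmission-failure rate
    (rest value ``p_f_rest``, jump ``delta_p_f``, floor ``p_min``, recovery
    ``tau_f_fail``).
    """
    mode: int
    tau_D: float = 0.0       # ms
    U_se: float = 0.0
    tau_F: float = 0.0       # ms
    U_b: float = 0.0
    U: float = 0.0
    p_f_rest: float = 0.0
    delta_p_f: float = 0.0
    p_min: float = 0.0
    tau_f_fail: float = 0.0  # ms

    def __post_init__(self):
        if self.mode in (STRONG, WEAK) and not (0 < self.U_se <= 1):
            raise ParameterError("depressing synapse needs 0 < U_se <= 1")
        if self.mode == FACIL and not (0 <= self.p_min <= self.p_f_rest <= 1):
            raise ParameterError("need 0 <= p_min <= p_f_rest <= 1")


STRONG_DEPRESSION = PlasticityParams(mode=STRONG, tau_D=150.0, U_se=0.2)
WEAK_DEPRESSION = PlasticityParams(mode=WEAK, tau_D=50.0, U_se=0.05)
FACILITATING = PlasticityParams(
    mode=FACIL, tau_D=100.0, U_se=0.0, tau_F=300.0, U_b=0.01, U=0.03,
    p_f_rest=0.5, delta_p_f=0.1, p_min=0.1, tau_f_fail=250.0)
NO_PLASTICITY = PlasticityParams(mode=STATIC)

PLASTICITY_BY_CLASS = {
    STATIC: NO_PLASTICITY,
    STRONG: STRONG_DEPRESSION,
    WEAK: WEAK_DEPRESSION,
    FACIL: FACILITATING,
}


@dataclass(frozen=True)
class CellTypeParams:
    """Statistical description of one neuron class (all heterogeneity rules)."""
    pop: int
    tau_m_mean: float          # ms, lognormal, rel SD 0.2
    v_T_mean: float            # mV, Gaussian, rel SD 0.1, redraw if <= v_R
    v_R: float = 10.0          # mV, reset / refractory clamp
    tau_ref0: float = 4.0      # ms, fixed floor of the refractory period
    tau_ref_extra_mean: float = 2.0  # ms, lognormal extra
    tau_ref_extra_sd: float = 1.0    # ms, absolute SD of the extra
    adapts: bool = False
    tau_a_mean: float = 0.0    # ms, lognormal, rel SD 0.2
    delta_a_mean: float = 0.0  # nA, lognormal, rel SD 0.2
    C_ext_th: int = 0          # thalamic external fan-in
    C_ext_bc: int = 0          # cortical-surround external fan-in
    J_ext: float = 0.0         # mV, mean exponential jump of external events
    rel_sd_tau_m: float = 0.2
    rel_sd_v_T: float = 0.1
    rel_sd_adapt: float = 0.2


RS_PARAMS = CellTypeParams(pop=RS, tau_m_mean=20.0, v_T_mean=20.0, adapts=True,
                           tau_a_mean=100.0, delta_a_mean=0.3,
                           C_ext_th=500, C_ext_bc=2000, J_ext=0.1)
FS_PARAMS = CellTypeParams(pop=FS, tau_m_mean=10.0, v_T_mean=20.0, adapts=False,
                           C_ext_th=500, C_ext_bc=1000, J_ext=0.2)
SOM_PARAMS = CellTypeParams(pop=SOM, tau_m_mean=20.0, v_T_mean=14.0, adapts=True,
                            tau_a_mean=50.0, delta_a_mean=0.2,
                            C_ext_th=0, C_ext_bc=0, J_ext=0.0)
# RS neurons of the differentiator readout network: weaker/faster adaptation
SB_PARAMS = dataclasses.replace(RS_PARAMS, pop=SB, tau_a_mean=50.0,
                                delta_a_mean=0.1)
INH_READ_PARAMS = dataclasses.replace(FS_PARAMS, pop=INH_READ)


@dataclass(frozen=True)
class ConnectionParams:
    """One ordered (target, source) chemical connection class."""
    fan_in: int                # synapses per target neuron
    J_mean: float              # mV, exponential mean of peak weights
    plasticity: int            # STATIC / STRONG / WEAK / FACIL
    delay_lo: float = 0.5      # ms
    delay_hi: float = 1.0      # ms


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes and connectivity of the BCN (defaults = published values)."""
    N_e: int = 2000
    N_i: int = 400
    N_s: int = 200
    # chemical connections keyed (target_pop, source_pop)
    connections: dict = field(default_factory=lambda: {
        (RS, RS): ConnectionParams(300, 0.10, STRONG),
        (RS, FS): ConnectionParams(200, 0.50, STRONG),
        (RS, SOM): ConnectionParams(100, 0.25, WEAK),
        (FS, RS): ConnectionParams(800, 0.20, STRONG),
        (FS, FS): ConnectionParams(200, 1.00, STRONG),
        (FS, SOM): ConnectionParams(50, 0.10, WEAK),
        (SOM, RS): ConnectionParams(1000, 0.10, FACIL),
        (SOM, FS): ConnectionParams(100, 0.25, STRONG),
    })
    # gap junctions: all-to-all within FS and within SOM, no self-coupling
    gap_J_mean: float = 0.05   # mV, exponential
    gap_delay_lo: float = 0.1  # ms
    gap_delay_hi: float = 0.5  # ms
    # external drive
    r_ext_th: float = 10.0     # Hz per thalamic input line
    r_ext_bc: float = 2.0      # Hz per cortical input line
    bias_mV: float = 10.0      # R_m * I_0, identical for all neurons
    # stimulation
    I_max: float = 5.0         # nA, maximum injected current

    def cell_params(self, pop: int) -> CellTypeParams:
        return {RS: RS_PARAMS, FS: FS_PARAMS, SOM: SOM_PARAMS,
                SB: SB_PARAMS, INH_READ: INH_READ_PARAMS}[pop]

    def pop_size(self, pop: int) -> int:
        return {RS: self.N_e, FS: self.N_i, SOM: self.N_s}[pop]


@dataclass(frozen=True)
class ReadoutConfig:
    """Readout-set sizes and filter constants shared by IR/DR/DNR."""
    N_read_RS: int = 1000
    N_read_FS: int = 100
    N_read_SOM: int = 100
    tau_ir: float = 20.0       # ms, integrator filter (tau_m,e)
    som_boost: float = 1.2     # SOM→readout weights 20% stronger than J_es
    delta_T: float = 10.0      # ms, differentiator lag / inhibitory extra delay
    tau_filter: float = 15.0   # ms, exponential smoothing of DR and DNR
    # differentiator readout network (DNR)
    N_B: int = 10000           # excitatory readout population SB
    N_I: int = 2000            # inhibitory readout population I
    C_ii_R: int = 200          # recurrent inhibitory fan-in per DNR neuron
    J_ei_R: float = 0.6        # mV, operating I→SB mean weight
    bc_rate_factor: float = 0.5  # cortical background rate halved in the DNR


@dataclass(frozen=True)
class SimConfig:
    """Integration and trial-protocol settings."""
    dt: float = 0.05           # ms
    T_idle: float = 1200.0     # ms simulated before stimulus onset (t=0)
    T_end: float = 1200.0      # ms simulated after stimulus onset
    T_w: float = 600.0         # ms detection window (0, T_w)
    record_dt: float = 1.0     # ms grid for traces
    N_trials: int = 10000


@dataclass(frozen=True)
class Preset:
    name: str
    network: NetworkConfig
    readout: ReadoutConfig
    sim: SimConfig


def published_default() -> Preset:
    return Preset("published_default", NetworkConfig(), ReadoutConfig(), SimConfig())


def desk_small() -> Preset:
    """Full-size BCN (its size sets the physics) with reduced trial counts and
    a scaled-down differentiator readout network (size there mostly sets the
    estimator variance of the population-rate average): SB at 1/10, I at 250
    so that the published recurrent fan-in of 200 remains feasible without
    replacement."""
    return Preset(
        "desk_small",
        NetworkConfig(),
        ReadoutConfig(N_B=1000, N_I=250),
        SimConfig(N_trials=400),
    )


PRESETS = {"published_default": published_default, "desk_small": desk_small}


def _preset_to_dict(p: Preset) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: clean(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {"|".join(POP_NAMES[i] for i in k) if isinstance(k, tuple)
                    else k: clean(v) for k, v in obj.items()}
        return obj
    return clean(p)


def load_preset(name_or_path: str) -> Preset:
    """Load a named preset, or a YAML file overriding preset fields."""
    if name_or_path in PRESETS:
        return PRESETS[name_or_path]()
    path = name_or_path
    if not str(path).endswith((".yaml", ".yml")):
        path = resources.files(__package__) / "presets" / f"{name_or_path}.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = PRESETS[raw.get("base", "published_default")]()
    net_raw = dict(raw.get("network", {}))
    if "connections" in net_raw:
        name_to_code = {v: k for k, v in POP_NAMES.items()}
        conns = {}
        for key, fields in net_raw["connections"].items():
            tgt, src = key.split("|")
            conns[(name_to_code[tgt], name_to_code[src])] = \
                ConnectionParams(**fields)
        net_raw["connections"] = conns
    net = dataclasses.replace(base.network, **net_raw)
    ro = dataclasses.replace(base.readout, **raw.get("readout", {}))
    sim = dataclasses.replace(base.sim, **raw.get("sim", {}))
    return Preset(raw.get("name", name_or_path), net, ro, sim)


def dump_preset(p: Preset, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_preset_to_dict(p), fh, sort_keys=False)
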