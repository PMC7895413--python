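"""Sampling and freezing of one network realization.

A :class:`NetworkRealization` is one frozen draw of all heterogeneous cellular
parameters, the connectivity (adjacency, per-synapse peak weights and delays),
the effective gap-junction coupling, the integrator-readout membership, and
the identity of the stimulated cell.  The same realization is reused across
stimulus types; only the external shot noise and the initial conditions are
redrawn per trial.

Weights are stored signed (sign given by the source population: RS and gap
junctions excitatory, FS and SOM inhibitory) in a compressed sparse row layout
indexed by *source* neuron, which is the natural layout for spike delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import params as P
from .params import (C_M, FACIL, FS, INH_READ, RS, SB, SOM, STATIC,
                     ConfigurationError, NetworkConfig, ReadoutConfig,
                     sample_lognormal, sample_thresholds)


def _sample_fan_in(n_src: int, fan_in: int, n_tgt: int, exclude_self: bool,
                   rng: np.random.Generator) -> np.ndarray:
    """(n_tgt, fan_in) source indices, drawn without replacement per target."""
    pool = n_src - 1 if exclude_self else n_src
    if fan_in > pool:
        raise ConfigurationError(
            f"fan-in {fan_in} exceeds available source pool {pool}")
    out = np.empty((n_tgt, fan_in), dtype=np.int32)
    for k in range(n_tgt):
        src = rng.choice(pool, size=fan_in, replace=False)
        if exclude_self:
            src = src + (src >= k)  # skip the target's own index
        out[k] = src
    return out


@dataclass
class IRReadout:
    """Frozen membership and weights of the integrator readout."""
    members: dict            # pop -> indices into the realization
    weights: dict            # pop -> positive peak weights [mV]
    config: ReadoutConfig


@dataclass
class NetworkRealization:
    config: NetworkConfig
    seed: int
    pop: np.ndarray          # int8 per neuron
    tau_m: np.ndarray        # ms
    v_T: np.ndarray          # mV
    tau_ref: np.ndarray      # ms (includes the 4 ms floor)
    tau_a: np.ndarray        # ms (1 where unused)
    delta_a: np.ndarray      # nA (0 = no adaptation)
    ext_rate_th: np.ndarray  # Hz, summed thalamic event rate per neuron
    ext_rate_bc: np.ndarray  # Hz, summed cortical event rate per neuron
    ext_jump: np.ndarray     # mV, exponential mean of external event amplitudes
    indptr: np.ndarray       # CSR by source neuron
    syn_tgt: np.ndarray
    syn_w: np.ndarray        # signed, mV
    syn_delay: np.ndarray    # ms
    syn_class: np.ndarray    # int8 plasticity class
    stim_target: int         # RS index receiving the injected current
    ir: IRReadout
    readout_config: ReadoutConfig
    has_dnr: bool = False

    @property
    def n_neurons(self) -> int:
        return self.pop.size

    def pop_indices(self, pop: int) -> np.ndarray:
        return np.nonzero(self.pop == pop)[0]

    def rm(self) -> np.ndarray:
        """Membrane resistance per neuron in mV/nA."""
        return self.tau_m / C_M

    def connection_probability(self, tgt_pop: int, src_pop: int) -> float:
        conn = self.config.connections[(tgt_pop, src_pop)]
        return conn.fan_in / self.config.pop_size(src_pop)

    def save(self, path: str) -> None:
        arrays = {k: getattr(self, k) for k in
                  ("pop", "tau_m", "v_T", "tau_ref", "tau_a", "delta_a",
                   "ext_rate_th", "ext_rate_bc", "ext_jump", "indptr",
                   "syn_tgt", "syn_w", "syn_delay", "syn_class")}
        arrays["meta"] = np.array([self.seed, self.stim_target,
                                   int(self.has_dnr)], dtype=np.int64)
        for pop, idx in self.ir.members.items():
            arrays[f"ir_members_{pop}"] = idx
            arrays[f"ir_weights_{pop}"] = self.ir.weights[pop]
        np.savez_compressed(path, **arrays)


def _cell_arrays(cfg: NetworkConfig, pops, rng):
    """Sample per-neuron cellular parameters for the given population layout."""
    pop = np.concatenate([np.full(n, p, dtype=np.int8) for p, n in pops])
    N = pop.size
    tau_m = np.empty(N)
    v_T = np.empty(N)
    tau_ref = np.empty(N)
    tau_a = np.ones(N)
    delta_a = np.zeros(N)
    rate_th = np.zeros(N)
    rate_bc = np.zeros(N)
    jump = np.zeros(N)
    off = 0
    for p, n in pops:
        cp = cfg.cell_params(p)
        s = slice(off, off + n)
        tau_m[s] = sample_lognormal(cp.tau_m_mean, cp.rel_sd_tau_m, n, rng)
        v_T[s] = sample_thresholds(cp.v_T_mean, cp.rel_sd_v_T, cp.v_R, n, rng)
        extra = sample_lognormal(cp.tau_ref_extra_mean,
                                 cp.tau_ref_extra_sd / cp.tau_ref_extra_mean,
                                 n, rng)
        tau_ref[s] = cp.tau_ref0 + extra
        if cp.adapts:
            tau_a[s] = sample_lognormal(cp.tau_a_mean, cp.rel_sd_adapt, n, rng)
            delta_a[s] = sample_lognormal(cp.delta_a_mean, cp.rel_sd_adapt, n, rng)
        rate_th[s] = cp.C_ext_th * cfg.r_ext_th
        rate_bc[s] = cp.C_ext_bc * cfg.r_ext_bc
        jump[s] = cp.J_ext
        off += n
    return pop, tau_m, v_T, tau_ref, tau_a, delta_a, rate_th, rate_bc, jump


_SIGN = {RS: +1.0, FS: -1.0, SOM: -1.0, SB: +1.0, INH_READ: -1.0}


class _SynapseBag:
    """Accumulates (src, tgt, w, delay, class) quintuples, then builds CSR."""

    def __init__(self):
        self.src, self.tgt, self.w, self.d, self.c = [], [], [], [], []

    def add_class(self, src_idx2d, tgt_offsets, J_mean, sign, lo, hi, cls, rng):
        n_tgt, fan_in = src_idx2d.shape
        n = n_tgt * fan_in
        self.src.append(src_idx2d.ravel())
        self.tgt.append(np.repeat(tgt_offsets, fan_in).astype(np.int32))
        self.w.append(sign * rng.exponential(J_mean, size=n))
        self.d.append(rng.uniform(lo, hi, size=n))
        self.c.append(np.full(n, cls, dtype=np.int8))

    def to_csr(self, n_neurons):
        src = np.concatenate(self.src)
        order = np.argsort(src, kind="stable")
        src = src[order]
        tgt = np.concatenate(self.tgt)[order]
        w = np.concatenate(self.w)[order].astype(np.float32)
        d = np.concatenate(self.d)[order].astype(np.float32)
        c = np.concatenate(self.c)[order]
        indptr = np.zeros(n_neurons + 1, dtype=np.int64)
        counts = np.bincount(src, minlength=n_neurons)
        indptr[1:] = np.cumsum(counts)
        return indptr, tgt, w, d, c


def _add_gap_junctions(bag, idx, cfg, rng):
    """Effective all-to-all spiking coupling without self-connections."""
    n = idx.size
    src = np.repeat(idx, n - 1)
    tgt = np.empty((n, n - 1), dtype=np.int32)
    for j in range(n):
        tgt[j] = np.delete(idx, j)
    m = src.size
    bag.src.append(src.astype(np.int32))
    bag.tgt.append(tgt.ravel())
    bag.w.append(rng.exponential(cfg.gap_J_mean, size=m))
    bag.d.append(rng.uniform(cfg.gap_delay_lo, cfg.gap_delay_hi, size=m))
    bag.c.append(np.full(m, STATIC, dtype=np.int8))


def build_ir_readout(realization_or_pops, readout_cfg: ReadoutConfig,
                     rng: np.random.Generator, cfg: NetworkConfig) -> IRReadout:
    """Sample integrator-readout membership and its depressing peak weights.

    The readout is treated as one grandmother RS cell: weights from the RS,
    FS and SOM readout sets are drawn from the corresponding within-network
    distributions (J_ee, J_ei, J_es), with the SOM weights boosted by 20%.
    """
    pop = realization_or_pops.pop if hasattr(realization_or_pops, "pop") \
        else realization_or_pops
    sizes = {RS: readout_cfg.N_read_RS, FS: readout_cfg.N_read_FS,
             SOM: readout_cfg.N_read_SOM}
    # readout weights follow the within-network class distributions; fall
    # back to the published means if a reduced config omits a class
    defaults = NetworkConfig().connections
    conn = {k: cfg.connections.get(k, defaults[k]) for k in defaults}
    j_means = {RS: conn[(RS, RS)].J_mean,
               FS: conn[(RS, FS)].J_mean,
               SOM: conn[(RS, SOM)].J_mean * readout_cfg.som_boost}
    members, weights = {}, {}
    for p, n_read in sizes.items():
        idx = np.nonzero(pop == p)[0]
        if n_read > idx.size:
            raise ConfigurationError(
                f"readout set size {n_read} exceeds population {idx.size}")
        members[p] = np.sort(rng.choice(idx, size=n_read, replace=False))
        weights[p] = rng.exponential(j_means[p], size=n_read)
    return IRReadout(members=members, weights=weights, config=readout_cfg)


def build_network(config: NetworkConfig | None = None,
                  seed: int = 0,
                  readout_config: ReadoutConfig | None = None,
                  with_dnr: bool = False) -> NetworkRealization:
    """Build one frozen realization of the BCN (optionally with the DNR).

    Fan-ins are fixed per target neuron, sources drawn uniformly without
    replacement (self-connections excluded).  With ``with_dnr`` the
    differentiator readout network (SB and I populations, feed-forward input
    from the BCN, recurrent inhibition, the extra inhibitory-pathway delay)
    is appended after the BCN populations.
    """
    cfg = config or NetworkConfig()
    rcfg = readout_config or ReadoutConfig()
    ss = np.random.SeedSequence(seed)
    (s_cells, s_conn, s_gap, s_ir, s_stim, s_dnr) = \
        [np.random.default_rng(s) for s in ss.spawn(6)]

    pops = [(RS, cfg.N_e), (FS, cfg.N_i), (SOM, cfg.N_s)]
    if with_dnr:
        pops += [(SB, rcfg.N_B), (INH_READ, rcfg.N_I)]
    (pop, tau_m, v_T, tau_ref, tau_a, delta_a,
     rate_th, rate_bc, jump) = _cell_arrays(cfg, pops, s_cells)
    if with_dnr:
        dnr = (pop == SB) | (pop == INH_READ)
        rate_bc[dnr] *= rcfg.bc_rate_factor

    offsets = {}
    off = 0
    for p, n in pops:
        offsets[p] = off
        off += n

    bag = _SynapseBag()
    for (tgt_pop, src_pop), conn in cfg.connections.items():
        n_tgt = cfg.pop_size(tgt_pop)
        n_src = cfg.pop_size(src_pop)
        srcs = _sample_fan_in(n_src, conn.fan_in, n_tgt,
                              exclude_self=(tgt_pop == src_pop), rng=s_conn)
        bag.add_class(srcs + offsets[src_pop],
                      np.arange(n_tgt, dtype=np.int32) + offsets[tgt_pop],
                      conn.J_mean, _SIGN[src_pop],
                      conn.delay_lo, conn.delay_hi, conn.plasticity, s_conn)
    _add_gap_junctions(bag, np.arange(cfg.N_i, dtype=np.int32) + offsets[FS],
                       cfg, s_gap)
    _add_gap_junctions(bag, np.arange(cfg.N_s, dtype=np.int32) + offsets[SOM],
                       cfg, s_gap)

    if with_dnr:
        _extend_with_dnr(bag, cfg, rcfg, offsets, s_dnr)

    indptr, tgt, w, d, c = bag.to_csr(pop.size)
    ir = build_ir_readout(pop, rcfg, s_ir, cfg)
    stim_target = int(s_stim.integers(cfg.N_e))

    return NetworkRealization(
        config=cfg, seed=seed, pop=pop, tau_m=tau_m, v_T=v_T, tau_ref=tau_ref,
        tau_a=tau_a, delta_a=delta_a, ext_rate_th=rate_th, ext_rate_bc=rate_bc,
        ext_jump=jump, indptr=indptr, syn_tgt=tgt, syn_w=w, syn_delay=d,
        syn_class=c, stim_target=stim_target, ir=ir, readout_config=rcfg,
        has_dnr=with_dnr)


def _extend_with_dnr(bag, cfg, rcfg, offsets, rng):
    """Feed-forward BCN→DNR and recurrent I→{SB,I} connections.

    Connection statistics follow the corresponding within-BCN class (SB
    behaves as an RS target, I as an FS target) with two exceptions: the mean
    I→SB weight is the tuned value ``J_ei_R`` and every connection from the
    BCN to I carries the additional transmission delay ``delta_T``.
    """
    ff_counts = {RS: rcfg.N_read_RS, FS: rcfg.N_read_FS, SOM: rcfg.N_read_SOM}
    for tgt_pop, proto in ((SB, RS), (INH_READ, FS)):
        n_tgt = rcfg.N_B if tgt_pop == SB else rcfg.N_I
        tgt_off = np.arange(n_tgt, dtype=np.int32) + offsets[tgt_pop]
        extra = rcfg.delta_T if tgt_pop == INH_READ else 0.0
        for src_pop, n_read in ff_counts.items():
            conn = cfg.connections[(proto, src_pop)]
            srcs = _sample_fan_in(cfg.pop_size(src_pop), n_read, n_tgt,
                                  exclude_self=False, rng=rng)
            bag.add_class(srcs + offsets[src_pop], tgt_off, conn.J_mean,
                          _SIGN[src_pop], conn.delay_lo + extra,
                          conn.delay_hi + extra, conn.plasticity, rng)
        # recurrent inhibition from I
        j_mean = rcfg.J_ei_R if tgt_pop == SB else cfg.connections[(FS, FS)].J_mean
        srcs = _sample_fan_in(rcfg.N_I, rcfg.C_ii_R, n_tgt,
                              exclude_self=(tgt_pop == INH_READ), rng=rng)
        bag.add_class(srcs + offsets[INH_READ], tgt_off, j_mean,
                      _SIGN[INH_READ], cfg.connections[(proto, FS)].delay_lo,
                      cfg.connections[(proto, FS)].delay_hi, P.STRONG, rng)


def load_network(path: str, config: NetworkConfig | None = None,
                 readout_config: ReadoutConfig | None = None) -> NetworkRealization:
    cfg = config or NetworkConfig()
    rcfg = readout_config or ReadoutConfig()
    with np.load(path) as z:
        meta = z["meta"]
        members = {}
        weights = {}
        for p in (RS, FS, SOM):
            members[p] = z[f"ir_members_{p}"]
            weights[p] = z[f"ir_weights_{p}"]
        return NetworkRealization(
            config=cfg, seed=int(meta[0]),
            stim_target=int(meta[1]), has_dnr=bool(meta[2]),
            ir=IRReadout(members, weights, rcfg), readout_config=rcfg,
            **{k: z[k] for k in
               ("pop", "tau_m", "v_T", "tau_ref", "tau_a", "delta_a",
                "ext_rate_th", "ext_rate_bc", "ext_jump", "indptr",
                "syn_tgt", "syn_w", "syn_delay", "syn_class")})
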