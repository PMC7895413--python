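"""Network integration: closed-form oracles, invariants, rate sanity."""

import dataclasses

import numpy as np
import pytest

import nanostim as ns
from nanostim import params as P
from nanostim.theory import shot_noise_rate


def _single_neuron_net(tau_m=20.0, v_T=20.0, tau_ref=6.0, adapt=False):
    """A network of one isolated RS cell with controlled parameters."""
    cfg = dataclasses.replace(P.NetworkConfig(), N_e=2, N_i=2, N_s=2,
                              connections={})
    rcfg = P.ReadoutConfig(N_read_RS=1, N_read_FS=1, N_read_SOM=1)
    net = ns.build_network(cfg, seed=0, readout_config=rcfg)
    net.ext_rate_th[:] = 0.0
    net.ext_rate_bc[:] = 0.0
    net.tau_m[:] = tau_m
    net.v_T[:] = v_T
    net.tau_ref[:] = tau_ref
    if not adapt:
        net.delta_a[:] = 0.0
    net.stim_target = 0
    return net


class TestSingleNeuronOracles:
    def test_leak_only_dynamics_are_silent(self):
        net = _single_neuron_net()
        net.config = dataclasses.replace(net.config, bias_mV=0.0)
        rec = ns.simulate_trial(net, trial_seed=1, t_start=-200, t_end=500)
        assert rec.neuron.size == 0

    def test_constant_suprathreshold_drive_matches_lif_closed_form(self):
        net = _single_neuron_net()
        # ~0.15 nA extra -> mu = 10 + R_m * I = 30 mV, suprathreshold
        rm = net.rm()[0]
        frac = 20.0 / rm / net.config.I_max
        stim = ns.step_stimulus(1000.0, frac)
        rec = ns.simulate_trial(net, stim, trial_seed=2, t_start=-50,
                                t_end=1000)
        t = rec.spikes_of(0)
        isi = np.diff(t)
        mu = 30.0
        expected = 6.0 + 20.0 * np.log((mu - 10.0) / (mu - 20.0))
        assert isi.size > 10
        assert np.allclose(isi, expected, atol=0.1)  # step quantization

    def test_shot_noise_driven_rate_matches_closed_form(self):
        """Cross-module oracle: the network kernel's shot-noise pathway
        reproduces the analytic shot-noise LIF rate within 3%."""
        net = _single_neuron_net(tau_m=20.0, tau_ref=6.0)
        net.ext_rate_th[0] = 5000.0
        net.ext_rate_bc[0] = 4000.0
        net.ext_jump[0] = 0.1
        count, T_tot = 0, 0.0
        for s in range(6):
            rec = ns.simulate_trial(net, trial_seed=100 + s, t_start=0.0,
                                    t_end=50_000.0)
            count += rec.spikes_of(0).size
            T_tot += 50.0
        sim_rate = count / T_tot
        th_rate = shot_noise_rate(0.1, 0.0, 9000.0, 0.0, mu0=10.0,
                                  tau_m=20.0, tau_ref=6.0)
        assert abs(sim_rate - th_rate) / th_rate < 0.03

    def test_same_trial_seed_reproduces_spikes_exactly(self):
        net = _single_neuron_net()
        net.ext_rate_th[:] = 3000.0
        net.ext_jump[:] = 0.15
        a = ns.simulate_trial(net, trial_seed=5, t_start=-100, t_end=2000)
        b = ns.simulate_trial(net, trial_seed=5, t_start=-100, t_end=2000)
        assert np.array_equal(a.neuron, b.neuron)
        assert np.array_equal(a.time, b.time)


class TestNetworkInvariants:
    def test_spontaneous_rate_ordering(self, bcn):
        rec = ns.simulate_trial(bcn, trial_seed=31, t_end=800.0)
        rates = ns.population_mean_rates([rec], window=(0.0, 800.0))
        assert rates[ns.FS] > rates[ns.SOM] > rates[ns.RS]

    def test_no_isi_below_the_refractory_period(self, bcn):
        rec = ns.simulate_trial(bcn, trial_seed=32, t_end=800.0)
        order = np.lexsort((rec.time, rec.neuron))
        neu, tim = rec.neuron[order], rec.time[order]
        same = neu[1:] == neu[:-1]
        isi = (tim[1:] - tim[:-1])[same]
        floor = bcn.tau_ref[neu[1:][same]]
        assert np.all(isi >= floor - 0.051)  # one-step quantization slack

    def test_step_halving_leaves_population_rates_unchanged(self, bcn):
        rates = {}
        for dt in (0.05, 0.025):
            sim = dataclasses.replace(P.SimConfig(), dt=dt)
            recs = [ns.simulate_trial(bcn, trial_seed=40 + s, sim=sim,
                                      t_end=800.0) for s in range(3)]
            rates[dt] = ns.population_mean_rates(recs, window=(0.0, 800.0))
        for p in (ns.RS, ns.FS, ns.SOM):
            assert rates[0.05][p] == pytest.approx(rates[0.025][p], rel=0.08)

    def test_oversized_step_rejected(self, bcn):
        sim = dataclasses.replace(P.SimConfig(), dt=0.2)  # > min gap delay
        with pytest.raises(P.ConfigurationError):
            ns.simulate_trial(bcn, trial_seed=1, sim=sim, t_end=0.0)


class TestEvokedStats:
    def test_zero_amplitude_stimulus_counts_spontaneous_spikes(self, bcn):
        stim = ns.step_stimulus(400.0, 0.0)
        recs = ns.simulate_batch(bcn, stim, 8, master_seed=77, t_end=420.0)
        st = ns.evoked_spike_stats(recs)
        assert st.mean_count < 1.5  # ~0.3 expected at the 0.8 Hz RS rate

    def test_window_and_trial_count_validation(self, bcn):
        recs = ns.simulate_batch(bcn, ns.step_stimulus(50, 0.2), 2,
                                 master_seed=3, t_end=60.0)
        with pytest.raises(ValueError):
            ns.evoked_spike_stats(recs[:1])
        with pytest.raises(ValueError):
            ns.evoked_spike_stats(recs, window=(100.0, 100.0))


class TestPopulationRate:
    def test_catch_trials_are_stationary(self, bcn_batches):
        t, r = ns.population_rate(bcn_batches["catch_a"][:40], ns.SOM)
        early = r[(t >= -900) & (t < -300)].mean()
        late = r[(t >= 0) & (t < 600)].mean()
        assert late == pytest.approx(early, rel=0.15)

    def test_excluding_the_stimulated_cell_removes_the_initial_rs_peak(
            self, bcn_batches):
        recs = bcn_batches["step400"]
        t, incl = ns.population_rate(recs, ns.RS)
        t, excl = ns.population_rate(recs, ns.RS,
                                     exclude=(recs[0].stim_target,))
        m_peak = (t > 0) & (t < 40)
        m_base = (t > -600) & (t < 0)
        peak_incl = incl[m_peak].max() - incl[m_base].mean()
        peak_excl = excl[m_peak].max() - excl[m_base].mean()
        assert peak_incl > 2.5 * max(peak_excl, 1e-9)

    def test_unknown_population_rejected(self, bcn_batches):
        with pytest.raises(ValueError):
            ns.population_rate(bcn_batches["catch_a"][:2], 9)
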