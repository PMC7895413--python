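"""Short-term plasticity: closed forms, worked examples, oracle identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanostim import plasticity as pl
from nanostim.oracles import (per_synapse_plasticity_oracle,
                              poisson_spike_train,
                              time_averaged_resources_mc,
                              tiny_plasticity_fixture)
from nanostim.params import (FACILITATING, STRONG_DEPRESSION, WEAK_DEPRESSION,
                             ParameterError)


class TestDepressionClosedForms:
    def test_full_resources_are_a_fixed_point(self):
        s = pl.PlasticityState(R=1.0, t=0.0)
        for dt in (0.1, 10.0, 1e6):
            assert pl.std_advance(s, dt, 150.0).R == pytest.approx(1.0)

    def test_relaxation_from_zero_over_one_time_constant(self):
        s = pl.PlasticityState(R=0.0, t=0.0)
        assert pl.std_advance(s, 150.0, 150.0).R == pytest.approx(1 - np.e**-1)

    def test_relaxation_closed_form_evaluation(self):
        s = pl.PlasticityState(R=0.8, t=0.0)
        out = pl.std_advance(s, 25.0, 150.0)
        assert out.R == pytest.approx(1 - 0.2 * np.exp(-1 / 6), abs=1e-12)
        assert out.R == pytest.approx(0.8307, abs=5e-4)

    def test_zero_release_probability_keeps_amplitude_one(self):
        factors = pl.depression_factors(
            np.arange(0, 200, 25.0),
            pl.PlasticityParams(mode=1, tau_D=150.0, U_se=1e-12))
        assert np.allclose(factors, 1.0, atol=1e-9)

    def test_backwards_advance_rejected(self):
        with pytest.raises(ParameterError):
            pl.std_advance(pl.PlasticityState(R=1.0, t=0.0), -1.0, 150.0)


class TestDepressionTrain:
    def test_eighth_psp_of_40hz_train_is_half_the_first(self):
        # strongly depressing synapse, 40 Hz regular drive
        t = np.arange(8) * 25.0
        f = pl.depression_factors(t, STRONG_DEPRESSION)
        assert f[0] == pytest.approx(1.0)
        assert f[7] / f[0] == pytest.approx(0.51, abs=0.01)

    def test_steady_state_of_40hz_train(self):
        t = np.arange(400) * 25.0
        f = pl.depression_factors(t, STRONG_DEPRESSION)
        e = np.exp(-25.0 / 150.0)
        R_star = (1 - e) / (1 - (1 - STRONG_DEPRESSION.U_se) * e)
        assert f[-1] == pytest.approx(R_star, rel=1e-9)
        assert R_star == pytest.approx(0.4756, abs=5e-4)


class TestMeanDepressionFactor:
    def test_zero_rate_gives_unity(self):
        assert pl.mean_depression_factor(0.0, 150.0, 0.2) == 1.0

    def test_formula_evaluation(self):
        assert pl.mean_depression_factor(10.0, 150.0, 0.2) == \
            pytest.approx(1 / 1.3)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            pl.mean_depression_factor(-1.0, 150.0, 0.2)

    @pytest.mark.parametrize("rate", [2.0, 10.0, 40.0])
    def test_matches_poisson_driven_time_average(self, rate):
        # PASTA: the stationary grid average of R equals the closed form
        mc = time_averaged_resources_mc(rate, STRONG_DEPRESSION,
                                        T_ms=2_000_000.0, seed=int(rate))
        th = pl.mean_depression_factor(rate, STRONG_DEPRESSION.tau_D,
                                       STRONG_DEPRESSION.U_se)
        assert abs(mc - th) / th < 0.02


class TestFacilitation:
    def test_first_spike_amplitude_after_long_silence(self):
        f, p = pl.facilitation_factors(np.array([0.0]), FACILITATING)
        Ub, U = FACILITATING.U_b, FACILITATING.U
        assert f[0] == pytest.approx((Ub + (1 - Ub) * U) / Ub)
        assert f[0] == pytest.approx(3.97, abs=0.005)
        assert p[0] == pytest.approx(FACILITATING.p_f_rest)

    def test_zero_facilitation_jump_reduces_to_depression(self):
        import dataclasses
        prm = dataclasses.replace(FACILITATING, U=0.0)
        t = np.arange(6) * 25.0
        f, _ = pl.facilitation_factors(t, prm)
        # u stays at U_b: amplitude factor equals R(t-)
        R, expected = 1.0, []
        for j in range(6):
            expected.append(R)
            R *= 1.0 - prm.U_b
            R = 1.0 - (1.0 - R) * np.exp(-25.0 / prm.tau_D)
        assert np.allclose(f, expected, rtol=1e-12)

    def test_facilitation_variable_is_nondecreasing_at_spikes(self):
        t = np.cumsum(np.random.default_rng(0).uniform(5, 50, 40))
        state = pl.rest_state(FACILITATING)
        import dataclasses as dc
        last_u = state.u
        for tt in t:
            dt = tt - state.t if np.isfinite(state.t) else np.inf
            state = dc.replace(pl.facilitation_advance(state, dt, FACILITATING),
                               t=tt)
            state, _ = pl.facilitation_on_spike(state, FACILITATING)
            assert state.u <= 1.0

    def test_expected_rs_to_som_amplitude_increases_over_40hz_train(self):
        # facilitation (with mean failure gate) beats depression over the
        # first eight spikes at the published parameters
        t = np.arange(8) * 25.0
        f, _ = pl.facilitation_factors(t, FACILITATING, mean_failures=True)
        assert np.all(np.diff(f) > 0)


class TestFailures:
    def test_full_jump_above_the_clip_region(self):
        assert pl.failure_jump(0.5, 0.1, 0.1) == pytest.approx(0.1)

    def test_clipped_jump_in_the_middle_branch(self):
        assert pl.failure_jump(0.15, 0.1, 0.1) == pytest.approx(0.05)
        # 0.15 jumps to exactly p_min = 0.10

    def test_no_jump_at_the_floor(self):
        assert pl.failure_jump(0.10, 0.1, 0.1) == 0.0

    def test_transmission_probability_uses_pre_spike_failure_rate(self):
        rng = np.random.default_rng(1)
        state = pl.PlasticityState(R=1.0, u=0.01, p_f=1.0, t=0.0)
        outcomes = [pl.failure_on_spike(state, FACILITATING, rng)[1]
                    for _ in range(200)]
        assert not any(outcomes)  # p_f = 1: everything fails


class TestMasterVariableIdentity:
    def test_per_synapse_oracle_matches_master_time_shift(self):
        """Each synapse's own state is an exact delayed copy of the master."""
        trains, delays = tiny_plasticity_fixture(n_neurons=10, T_ms=2000.0)
        for params in (STRONG_DEPRESSION, WEAK_DEPRESSION, FACILITATING):
            for train, delay in zip(trains, delays):
                if params.mode == 3:
                    master, p_pre = pl.facilitation_factors(train, params)
                else:
                    master = pl.depression_factors(train, params)
                oracle = per_synapse_plasticity_oracle(train, delay, params)
                assert np.max(np.abs(oracle.factor - master)) < 1e-12 \
                    if train.size else True

    def test_empty_train_stays_at_rest(self):
        oracle = per_synapse_plasticity_oracle(np.array([]), 0.7,
                                               STRONG_DEPRESSION)
        assert oracle.factor.size == 0


@settings(max_examples=25, deadline=None)
@given(isis=st.lists(st.floats(0.1, 500.0), min_size=1, max_size=60),
       mode=st.sampled_from(["strong", "weak", "facil"]))
def test_state_bounds_for_arbitrary_spike_trains(isis, mode):
    """R in (0,1], u in [U_b,1), p_f in [p_min, p_f_rest] at all event times."""
    t = np.cumsum(np.asarray(isis))
    if mode == "facil":
        prm = FACILITATING
        f, p_pre = pl.facilitation_factors(t, prm)
        assert np.all(p_pre >= prm.p_min - 1e-12)
        assert np.all(p_pre <= prm.p_f_rest + 1e-12)
        assert np.all(f > 0)
        # amplitude factor bounded by max facilitation over baseline
        assert np.all(f <= 1.0 / prm.U_b)
    else:
        prm = STRONG_DEPRESSION if mode == "strong" else WEAK_DEPRESSION
        f = pl.depression_factors(t, prm)
        assert np.all(f > 0)
        assert np.all(f <= 1.0)
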