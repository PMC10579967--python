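"""Model core: TF input function, ODE right-hand side, steady states,
protocols and parameter serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromopulse.model import equilibrate, ode_rhs, steady_state, steady_state_chromatin, tf_level
from chromopulse.params import (
    AdaptationParams,
    GeneKinetics,
    ModelState,
    StimulusProtocol,
    dump_config,
    load_config,
)


class TestTFLevel:
    def test_saturates_at_one_for_large_stimulus(self, plain_kinetics):
        assert tf_level(1e6, plain_kinetics) == pytest.approx(1.0)

    def test_reduces_to_plain_tanh_when_adaptation_disabled(self, plain_kinetics):
        adapt = AdaptationParams.disabled()
        for ifng in (0.0, 0.1, 1.0, 10.0):
            expected = np.tanh(plain_kinetics.alpha * (ifng + plain_kinetics.Kd))
            assert tf_level(ifng, plain_kinetics, adapt, regP=1e6) == pytest.approx(expected, rel=1e-15)

    def test_half_suppression_at_threshold_with_unit_exponent(self, plain_kinetics):
        adapt = AdaptationParams(
            a_regM=1, a_regP=1, delta_regM=1, delta_regP=1, reg_thr=20.0, c1=1.0, c2=1.0, enabled=True
        )
        full = tf_level(5.0, plain_kinetics)
        assert tf_level(5.0, plain_kinetics, adapt, regP=20.0) == pytest.approx(full / 2)

    def test_zero_at_zero_input_with_zero_offset(self, plain_kinetics):
        kin = plain_kinetics.replace(alpha=1.0, Kd=0.0)
        assert tf_level(0.0, kin) == 0.0

    def test_rejects_negative_inputs(self, plain_kinetics):
        with pytest.raises(ValueError):
            tf_level(-1.0, plain_kinetics)
        with pytest.raises(ValueError):
            tf_level(1.0, plain_kinetics, AdaptationParams.disabled(), regP=-2.0)

    @settings(deadline=None, max_examples=50)
    @given(
        ifng=st.lists(st.floats(0, 100), min_size=2, max_size=6),
        regp=st.lists(st.floats(0, 1e4), min_size=2, max_size=6),
    )
    def test_monotone_in_stimulus_and_regulator(self, ifng, regp, plain_kinetics, plain_adaptation):
        ifng, regp = np.sort(ifng), np.sort(regp)
        up = tf_level(ifng, plain_kinetics, plain_adaptation, regP=0.0)
        assert np.all(np.diff(up) >= -1e-15)
        down = np.array([tf_level(1.0, plain_kinetics, plain_adaptation, regP=r) for r in regp])
        assert np.all(np.diff(down) <= 1e-15)


class TestOdeRhs:
    def test_fixed_point_with_no_input_and_no_offset(self, plain_kinetics):
        kin = plain_kinetics.replace(Kd=0.0)
        proto = StimulusProtocol.constant(0.0)
        deriv = ode_rhs(1.0, np.array([2.0, 0, 0, 0, 0, 0, 0]), kin, AdaptationParams.disabled(), proto)
        assert np.allclose(deriv, 0.0)

    @settings(deadline=None, max_examples=30)
    @given(state=st.lists(st.floats(0, 50), min_size=7, max_size=7), t=st.floats(0, 30))
    def test_chromatin_derivatives_sum_to_zero(self, state, t, plain_kinetics, plain_adaptation):
        proto = StimulusProtocol.constant(10.0)
        d = ode_rhs(t, np.asarray(state), plain_kinetics, plain_adaptation, proto)
        assert d[0] + d[1] + d[2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_term_by_term_hand_evaluation(self):
        # independent hand evaluation of every printed term at a fixed state
        kin = GeneKinetics(k1=0.7, k2=0.3, k3=1.1, k4=0.4, k5=6.0, k6=2.5,
                           deltaM=1.2, deltaP=0.25, alpha=0.5, Kd=0.2)
        adapt = AdaptationParams(a_regM=12.0, a_regP=1.5, delta_regM=0.6,
                                 delta_regP=0.3, reg_thr=25.0, c1=2.0, c2=0.5, enabled=True)
        state = np.array([0.9, 0.7, 0.4, 3.0, 20.0, 5.0, 40.0])
        ifng = 4.0
        tf = np.tanh(0.5 * (4.0 + 0.2)) / (1.0 + (40.0 / 25.0) ** 2.0)
        expected = np.array([
            0.3 * 0.7 - 0.7 * tf * 0.9,
            0.7 * tf * 0.9 - 0.3 * 0.7 - 1.1 * tf * 0.7 + 0.4 * 0.4,
            1.1 * tf * 0.7 - 0.4 * 0.4,
            6.0 * 0.4 - 1.2 * 3.0,
            2.5 * 3.0 - 0.25 * 20.0,
            12.0 * tf**0.5 / (1.0 + tf**0.5) - 0.6 * 5.0,
            1.5 * 5.0 - 0.3 * 40.0,
        ])
        got = ode_rhs(0.0, state, kin, adapt, StimulusProtocol.constant(ifng))
        np.testing.assert_allclose(got, expected, rtol=1e-14)

    def test_regulator_frozen_when_adaptation_disabled(self, plain_kinetics):
        state = np.array([1.0, 0.5, 0.5, 2.0, 10.0, 3.0, 7.0])
        d = ode_rhs(0.0, state, plain_kinetics, AdaptationParams.disabled(), StimulusProtocol.constant(10.0))
        assert d[5] == 0.0 and d[6] == 0.0


class TestSteadyStateChromatin:
    def test_all_closed_without_tf(self, plain_kinetics):
        assert steady_state_chromatin(plain_kinetics, 0.0) == (2.0, 0.0, 0.0)

    def test_balanced_rates_give_equal_occupancy_ratios(self):
        kin = GeneKinetics(k1=1.0, k2=0.5, k3=2.0, k4=1.0, k5=1, k6=1,
                           deltaM=1, deltaP=1, alpha=1, Kd=0)
        c, ou, oi = steady_state_chromatin(kin, 0.5)  # k1*tf = k2, k3*tf = k4
        assert (c, ou, oi) == pytest.approx((2 / 3, 2 / 3, 2 / 3))

    @settings(deadline=None, max_examples=30)
    @given(
        rates=st.lists(st.floats(0.05, 5.0), min_size=4, max_size=4),
        tf=st.floats(0.01, 1.0),
    )
    def test_matches_nullspace_of_rate_matrix(self, rates, tf):
        # independent linear-algebra oracle for the 3-state chain
        k1, k2, k3, k4 = rates
        kin = GeneKinetics(k1=k1, k2=k2, k3=k3, k4=k4, k5=1, k6=1,
                           deltaM=1, deltaP=1, alpha=1, Kd=0)
        A = np.array([
            [-k1 * tf, k2, 0.0],
            [k1 * tf, -k2 - k3 * tf, k4],
            [0.0, k3 * tf, -k4],
        ])
        _, _, vt = np.linalg.svd(A)
        null = np.abs(vt[-1])
        expected = 2.0 * null / null.sum()
        got = steady_state_chromatin(kin, tf)
        np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-10)
        assert sum(got) == pytest.approx(2.0)


class TestEquilibrate:
    def test_zero_offset_rests_fully_closed(self, plain_kinetics):
        st0 = equilibrate(plain_kinetics.replace(Kd=0.0), AdaptationParams.disabled())
        np.testing.assert_allclose(st0.to_array(), [2, 0, 0, 0, 0, 0, 0], atol=1e-12)

    def test_matches_closed_form_without_adaptation(self, plain_kinetics):
        st0 = equilibrate(plain_kinetics, AdaptationParams.disabled())
        tf = np.tanh(plain_kinetics.alpha * plain_kinetics.Kd)
        c, ou, oi = steady_state_chromatin(plain_kinetics, tf)
        assert (st0.C, st0.OU, st0.OI) == pytest.approx((c, ou, oi), rel=1e-9)

    def test_residual_below_tolerance(self, plain_kinetics, plain_adaptation):
        st0 = equilibrate(plain_kinetics, plain_adaptation)
        d = ode_rhs(0.0, st0.to_array(), plain_kinetics, plain_adaptation,
                    StimulusProtocol.constant(0.0))
        assert np.abs(d).max() < 1e-7

    def test_agrees_with_long_integration(self, plain_kinetics, plain_adaptation):
        from chromopulse.deterministic import integrate

        st0 = steady_state(plain_kinetics, plain_adaptation, 10.0)
        t = np.linspace(0.0, 400.0, 41)
        traj = integrate(plain_kinetics, plain_adaptation, StimulusProtocol.constant(10.0, horizon=400.0), t)
        final = np.array([traj[s][-1] for s in ("C", "OU", "OI", "M", "P", "regM", "regP")])
        np.testing.assert_allclose(final, st0.to_array(), rtol=1e-6, atol=1e-6)


class TestStimulusProtocol:
    def test_concentration_queries(self):
        p = StimulusProtocol.two_pulse()
        assert p.ifng_at(-1.0) == 0.0
        assert p.ifng_at(2.0) == 10.0
        assert p.ifng_at(5.0) == 0.0
        assert p.ifng_at(15.0) == 10.0
        assert p.ifng_at(20.0) == 0.0
        np.testing.assert_array_equal(p.ifng([2.0, 5.0]), [10.0, 0.0])

    def test_shorthand_strings(self):
        assert StimulusProtocol.from_string("constant:10").segments == [(0.0, 31.0, 10.0)]
        assert StimulusProtocol.from_string("pulse:0-4:10").segments == [(0.0, 4.0, 10.0)]
        assert StimulusProtocol.from_string("twopulse:0-4,14-18:10").segments == [
            (0.0, 4.0, 10.0),
            (14.0, 18.0, 10.0),
        ]
        with pytest.raises(ValueError):
            StimulusProtocol.from_string("ramp:0-4:10")

    def test_rejects_overlaps_and_negative_concentration(self):
        with pytest.raises(ValueError):
            StimulusProtocol(segments=[(0, 5, 10), (4, 8, 10)])
        with pytest.raises(ValueError):
            StimulusProtocol(segments=[(0, 5, -1)])

    def test_model_state_validation(self):
        ModelState(1.0, 0.5, 0.5).validate(n_loci=2)
        with pytest.raises(ValueError):
            ModelState(1.0, 0.5, 0.2).validate(n_loci=2)
        with pytest.raises(ValueError):
            ModelState(-0.1, 1.1, 1.0).validate()


def test_config_round_trip(tmp_path, plain_kinetics, plain_adaptation):
    proto = StimulusProtocol.two_pulse()
    path = tmp_path / "model.yaml"
    dump_config(path, kinetics=plain_kinetics, adaptation=plain_adaptation, protocol=proto)
    loaded = load_config(path)
    assert loaded["kinetics"] == plain_kinetics
    assert loaded["adaptation"] == plain_adaptation
    assert loaded["protocol"].segments == proto.segments
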