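"""Deterministic integration, data normalization, objective and fitting."""

import numpy as np
import pytest

from chromopulse.deterministic import (
    REFERENCE_CHIP_SCALE_FACTORS,
    Condition,
    ConditionData,
    chip_scale_factor,
    fit,
    integrate,
    loss,
    prepare_dataset,
    rescale_to_peak,
)
from chromopulse.model import equilibrate, steady_state_chromatin, tf_level
from chromopulse.params import AdaptationParams, StimulusProtocol
from chromopulse.stochastic import _pack_params


def _rk4_oracle(kin, adapt, protocol, t_grid, y0, h=1e-3):
    """Independent brute-force fixed-step RK4 on the printed equations,
    written without reference to the package integrators."""

    def rhs(ifng, y):
        C, OU, OI, M, P, regM, regP = y
        tf = np.tanh(kin.alpha * (ifng + kin.Kd))
        if adapt.enabled:
            tf /= 1.0 + (max(regP, 0.0) / adapt.reg_thr) ** adapt.c1
        dC = kin.k2 * OU - kin.k1 * tf * C
        dOU = kin.k1 * tf * C - kin.k2 * OU - kin.k3 * tf * OU + kin.k4 * OI
        dOI = kin.k3 * tf * OU - kin.k4 * OI
        dM = kin.k5 * OI - kin.deltaM * M
        dP = kin.k6 * M - kin.deltaP * P
        if adapt.enabled:
            h_ = tf**adapt.c2 if tf > 0 else 0.0
            dregM = adapt.a_regM * h_ / (1 + h_) - adapt.delta_regM * regM
            dregP = adapt.a_regP * regM - adapt.delta_regP * regP
        else:
            dregM = dregP = 0.0
        return np.array([dC, dOU, dOI, dM, dP, dregM, dregP])

    # knots: output times plus stimulus switch points, stepped in h-chunks
    knots = np.unique(np.concatenate([t_grid, protocol.switch_times()]))
    knots = knots[(knots >= t_grid[0]) & (knots <= t_grid[-1])]
    y = np.asarray(y0, float).copy()
    out = {float(t_grid[0]): y.copy()}
    for a, b in zip(knots[:-1], knots[1:]):
        ifng = protocol.ifng_at((a + b) / 2)  # constant within the interval
        n = max(1, int(np.ceil((b - a) / h)))
        hh = (b - a) / n
        for _ in range(n):
            k1_ = rhs(ifng, y)
            k2_ = rhs(ifng, y + hh / 2 * k1_)
            k3_ = rhs(ifng, y + hh / 2 * k2_)
            k4_ = rhs(ifng, y + hh * k3_)
            y = y + hh / 6 * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
        out[float(b)] = y.copy()
    return np.array([out[float(t)] for t in t_grid])


class TestIntegrate:
    def test_constant_at_fixed_point_under_zero_stimulus(self, plain_kinetics, plain_adaptation):
        t = np.linspace(0, 20, 21)
        traj = integrate(plain_kinetics, plain_adaptation, StimulusProtocol.constant(0.0), t)
        for s in ("C", "OU", "OI", "M", "P", "regM", "regP"):
            assert np.ptp(traj[s]) < 1e-6

    def test_long_time_limits_match_closed_forms(self, plain_kinetics):
        adapt = AdaptationParams.disabled()
        kin = plain_kinetics
        proto = StimulusProtocol.constant(10.0, horizon=300.0)
        t = np.linspace(0, 300, 31)
        traj = integrate(kin, adapt, proto, t)
        tf = tf_level(10.0, kin)
        c, ou, oi = steady_state_chromatin(kin, tf)
        assert traj["OI"][-1] == pytest.approx(oi, rel=1e-6)
        assert traj["M"][-1] == pytest.approx(kin.k5 * oi / kin.deltaM, rel=1e-6)
        assert traj["P"][-1] == pytest.approx(kin.k6 * kin.k5 * oi / (kin.deltaM * kin.deltaP), rel=1e-6)

    @pytest.mark.parametrize("protocol", [
        StimulusProtocol.constant(10.0),
        StimulusProtocol.pulse(0.0, 4.0, 10.0),
        StimulusProtocol.two_pulse(),
    ], ids=["constant", "pulse", "two_pulse"])
    def test_agrees_with_independent_rk4_oracle(self, protocol, plain_kinetics, plain_adaptation):
        t = np.arange(-2.0, 32.0, 2.0)
        y0 = equilibrate(plain_kinetics, plain_adaptation)
        traj = integrate(plain_kinetics, plain_adaptation, protocol, t, y0=y0)
        oracle = _rk4_oracle(plain_kinetics, plain_adaptation, protocol, t, y0.to_array())
        got = np.column_stack([traj[s] for s in ("C", "OU", "OI", "M", "P", "regM", "regP")])
        scale = np.abs(oracle).max(axis=0) + 1e-12
        assert np.max(np.abs(got - oracle) / scale) < 1e-5

    def test_fast_path_matches_adaptive_solver(self, gene_preset, hourly_grid, constant10):
        _, kin, adapt = gene_preset
        a = integrate(kin, adapt, constant10, hourly_grid)
        b = integrate(kin, adapt, constant10, hourly_grid, method="rk4")
        for s in ("C", "OU", "OI", "M", "P", "regM", "regP"):
            scale = np.abs(a[s]).max() + 1e-12
            assert np.max(np.abs(a[s] - b[s])) / scale < 1e-6

    def test_conservation_and_nonnegativity_along_trajectory(self, gene_preset, hourly_grid):
        _, kin, adapt = gene_preset
        traj = integrate(kin, adapt, StimulusProtocol.two_pulse(), hourly_grid)
        total = traj["C"] + traj["OU"] + traj["OI"]
        assert np.abs(total - kin.n_loci).max() < 1e-6
        for s in ("C", "OU", "OI", "M", "P", "regM", "regP"):
            assert np.all(traj[s] >= -1e-9)


class TestNormalization:
    def test_rescale_halves_a_double_peak(self):
        scaled, f = rescale_to_peak(np.array([0.0, 80.0, 40.0]), target=40.0)
        assert f == 0.5
        assert scaled.max() == 40.0

    def test_rescale_identity_when_already_at_target(self):
        trace = np.array([1.0, 40.0, 3.0])
        scaled, f = rescale_to_peak(trace, target=40.0)
        assert f == 1.0
        np.testing.assert_array_equal(scaled, trace)

    def test_rescale_rejects_nonpositive_traces(self):
        with pytest.raises(ValueError):
            rescale_to_peak(np.array([0.0, -1.0]))

    def test_chip_scale_factor_is_ratio_of_maxima(self):
        assert chip_scale_factor(40.0, 20.0) == 2.0
        assert chip_scale_factor(7.0, 7.0) == 1.0
        with pytest.raises(ValueError):
            chip_scale_factor(0.0, 5.0)

    def test_reference_scale_factors_are_the_published_constants(self):
        assert REFERENCE_CHIP_SCALE_FACTORS == {
            "IRF1": 1.7757, "CXCL10": 3.1105, "CXCL9": 3.3009,
        }

    def test_prepare_dataset_scales_chip_to_plate_and_peaks_at_target(self):
        t = np.arange(-2.0, 10.0)
        curve = np.clip(t, 0, None) * 4.0  # peak 36
        plate = ConditionData(
            Condition("conc_10", StimulusProtocol.constant(10.0), "plate"), t, 2.0 * curve
        )
        chip = ConditionData(
            Condition("dur_constant", StimulusProtocol.constant(10.0), "chip"), t, curve
        )
        prepared, info = prepare_dataset([plate, chip], target=40.0)
        assert info["chip_scale"] == pytest.approx(2.0)
        assert max(cd.mean.max() for cd in prepared) == pytest.approx(40.0)
        # both conditions coincide after normalization
        np.testing.assert_allclose(prepared[0].mean, prepared[1].mean, rtol=1e-12)


@pytest.fixture(scope="module")
def small_synth_dataset(plain_kinetics, plain_adaptation):
    """Noiseless model-generated means over a compact condition set."""
    t = np.arange(-2.0, 32.0)
    conds = [
        Condition("lo", StimulusProtocol.constant(1.0), "plate"),
        Condition("hi", StimulusProtocol.constant(10.0), "plate"),
        Condition("pulse4", StimulusProtocol.pulse(0, 4, 10.0), "chip"),
    ]
    data = []
    for c in conds:
        traj = integrate(plain_kinetics, plain_adaptation, c.protocol, t, method="rk4")
        data.append(ConditionData(c, t, traj["P"]))
    return data


class TestLossAndFit:
    def _theta(self, kin):
        from chromopulse.deterministic import FIT_PARAM_NAMES

        return np.log10([getattr(kin, n) for n in FIT_PARAM_NAMES])

    def test_loss_is_zero_at_generating_parameters(self, small_synth_dataset, plain_kinetics, plain_adaptation):
        l0 = loss(self._theta(plain_kinetics), small_synth_dataset, plain_kinetics, plain_adaptation)
        assert l0 < 1e-10

    def test_loss_increases_under_local_perturbation(self, small_synth_dataset, plain_kinetics, plain_adaptation):
        base = self._theta(plain_kinetics)
        for i in range(len(base)):
            for sign in (-1, 1):
                theta = base.copy()
                theta[i] += sign * 0.05
                assert loss(theta, small_synth_dataset, plain_kinetics, plain_adaptation) > 1e-6

    def test_loss_invariant_to_condition_order(self, small_synth_dataset, plain_kinetics, plain_adaptation):
        theta = self._theta(plain_kinetics) + 0.1
        a = loss(theta, small_synth_dataset, plain_kinetics, plain_adaptation)
        b = loss(theta, small_synth_dataset[::-1], plain_kinetics, plain_adaptation)
        assert a == pytest.approx(b, rel=1e-12)

    def test_masked_timepoints_contribute_nothing(self, small_synth_dataset, plain_kinetics, plain_adaptation):
        # corrupt data beyond 12 h, then mask those points out
        cd = small_synth_dataset[1]
        corrupted = cd.mean.copy()
        corrupted[cd.time > 12.0] += 1e3
        masked = ConditionData(
            Condition(cd.condition.label, cd.condition.protocol, "plate", fit_mask=[(-2.0, 12.0)]),
            cd.time,
            corrupted,
        )
        l0 = loss(self._theta(plain_kinetics), [masked], plain_kinetics, plain_adaptation)
        assert l0 < 1e-10

    def test_fit_from_truth_converges_to_zero_loss(self, small_synth_dataset, plain_kinetics, plain_adaptation):
        res = fit(small_synth_dataset, plain_kinetics, plain_adaptation, maxfev=600)
        assert res.loss < 1e-6
        assert res.converged

    def test_fit_respects_bounds_excluding_truth(self, small_synth_dataset, plain_kinetics, plain_adaptation):
        bounds = {"k5": (8.0, 20.0)}  # truth k5 = 5 excluded
        res = fit(
            small_synth_dataset,
            plain_kinetics,
            plain_adaptation,
            bounds=bounds,
            init={"k5": 10.0},
            maxfev=400,
        )
        assert 8.0 <= res.kinetics.k5 <= 20.0
        assert res.loss > 1e-8

    def test_integration_failure_returns_penalty_not_exception(self, small_synth_dataset, plain_kinetics, plain_adaptation):
        theta = self._theta(plain_kinetics)
        theta[:] = np.log10(1e3)  # extreme rates
        val = loss(theta, small_synth_dataset, plain_kinetics, plain_adaptation)
        assert np.isfinite(val)


class TestDatasetIO:
    def test_mean_trace_table_round_trip(self, small_synth_dataset, tmp_path):
        from chromopulse.deterministic import read_dataset, write_dataset

        path = tmp_path / "means.csv"
        write_dataset(small_synth_dataset, path)
        back = read_dataset(path, [cd.condition for cd in small_synth_dataset])
        for a, b in zip(small_synth_dataset, back):
            np.testing.assert_allclose(a.mean, b.mean, rtol=1e-12)
            assert a.condition.label == b.condition.label

    def test_fit_report_serializes(self, small_synth_dataset, plain_kinetics, plain_adaptation, tmp_path):
        import json

        res = fit(small_synth_dataset, plain_kinetics, plain_adaptation, maxfev=50)
        path = tmp_path / "fit.json"
        res.save(path)
        doc = json.loads(path.read_text())
        assert set(doc) >= {"kinetics", "adaptation", "loss", "converged", "bounds"}
        assert doc["kinetics"]["k1"] == res.kinetics.k1
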