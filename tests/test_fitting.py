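"""Estimation: round-trips, fitting modes, model selection, hysteresis."""

import numpy as np
import pytest

from foldscale.exceptions import (
    IndistinguishableStates,
    NoOverlap,
    NoTransition,
)
from foldscale.fitting import (
    SharedMGlobalFitter,
    ThreeStateFitter,
    TwoStateFitter,
    assess_hysteresis,
    fit_global_shared_m,
    fit_three_state,
    fit_two_state,
    select_model,
)
from foldscale.models import Baselines, ThermoThreeState, ThermoTwoState, TitrationCurve
from foldscale.simulate import (
    NoiseModel,
    default_baselines,
    default_grid,
    simulate_three_state_curve,
    simulate_two_state_curve,
)


class TestTwoState:
    @pytest.mark.parametrize("mode", ["direct", "two_stage"])
    def test_noiseless_round_trip(self, two_state_truth, baselines, mode):
        curve = simulate_two_state_curve(two_state_truth, baselines)
        res = fit_two_state(curve, mode=mode)
        assert res.thermo.dG0 == pytest.approx(8.0, rel=1e-4)
        assert res.thermo.m == pytest.approx(2.5, rel=1e-4)
        assert res.thermo.Cm == pytest.approx(3.2, rel=1e-4)

    def test_modes_agree_on_noiseless_data(self, two_state_truth, baselines):
        curve = simulate_two_state_curve(two_state_truth, baselines)
        d = fit_two_state(curve, mode="direct")
        s = fit_two_state(curve, mode="two_stage")
        assert d.thermo.dG0 == pytest.approx(s.thermo.dG0, rel=1e-6)
        assert d.thermo.m == pytest.approx(s.thermo.m, rel=1e-6)

    def test_flat_curve_reports_no_transition(self, grid):
        curve = TitrationCurve("flat", grid, np.full(grid.size, 0.8))
        with pytest.raises(NoTransition):
            fit_two_state(curve)

    def test_noisy_recovery_within_three_standard_errors(self, two_state_truth,
                                                         baselines):
        curve = simulate_two_state_curve(two_state_truth, baselines,
                                         noise=NoiseModel(0.02, 314))
        res = fit_two_state(curve)
        assert abs(res.thermo.dG0 - 8.0) < 3 * res.param_errors["dG0"]
        assert abs(res.thermo.m - 2.5) < 3 * res.param_errors["m"]

    def test_fit_invariant_to_affine_signal_rescaling(self, two_state_truth,
                                                      baselines):
        c = simulate_two_state_curve(two_state_truth, baselines,
                                     noise=NoiseModel(0.02, 77))
        r1 = fit_two_state(c)
        c2 = TitrationCurve(c.mutant_id, c.denaturant, 37.0 * c.signal + 5.0)
        r2 = fit_two_state(c2)
        assert r2.thermo.dG0 == pytest.approx(r1.thermo.dG0, rel=1e-8)
        assert r2.thermo.m == pytest.approx(r1.thermo.m, rel=1e-8)

    def test_descending_or_ascending_signal_fits_identically(self, two_state_truth):
        # swapped baselines: signal rises upon unfolding instead of falling
        up = Baselines(yF=0.35, mF=-0.01, yU=1.0, mU=-0.02)
        c = simulate_two_state_curve(two_state_truth, up, noise=NoiseModel(0.01, 5))
        res = fit_two_state(c)
        assert res.thermo.dG0 == pytest.approx(8.0, rel=0.1)

    def test_sklearn_estimator_interface(self, two_state_truth, baselines, grid):
        c = simulate_two_state_curve(two_state_truth, baselines)
        est = TwoStateFitter().fit(grid.reshape(-1, 1), c.signal)
        assert est.thermo_.dG0 == pytest.approx(8.0, rel=1e-4)
        pred = est.predict(grid)
        assert np.max(np.abs(pred - c.signal)) < 1e-8
        assert est.get_params()["mode"] == "direct"


class TestThreeState:
    def test_noiseless_round_trip(self, three_state_truth, baselines3):
        curve = simulate_three_state_curve(three_state_truth, baselines3)
        res = fit_three_state(curve)
        t = res.thermo
        for got, want in [(t.dG1, 3.0), (t.m1, 1.5), (t.dG2, 5.0), (t.m2, 1.2)]:
            assert got == pytest.approx(want, rel=1e-3)
        assert t.dG_total == pytest.approx(8.0, rel=1e-3)

    def test_two_state_data_has_invisible_intermediate(self, two_state_truth,
                                                       baselines):
        curve = simulate_two_state_curve(two_state_truth, baselines,
                                         noise=NoiseModel(0.01, 9))
        try:
            res = fit_three_state(curve)
        except IndistinguishableStates:
            return
        assert res.max_intermediate_population < 0.35

    def test_shared_slope_constraint_ties_intermediate_slope(self,
                                                             three_state_truth,
                                                             baselines3):
        curve = simulate_three_state_curve(three_state_truth, baselines3)
        res = fit_three_state(curve, shared_slope=True)
        assert res.baselines.mI == res.baselines.mF
        # slight model mismatch (true mI != mF) but totals still close
        assert res.thermo.dG_total == pytest.approx(8.0, rel=0.05)

    def test_sum_recovered_despite_split_ambiguity(self, baselines3):
        # repartitioned truth with the same total and same midpoints ordering
        truth = ThermoThreeState(dG1=2.5, m1=1.25, dG2=5.5, m2=1.3)
        curve = simulate_three_state_curve(truth, baselines3)
        res = fit_three_state(curve)
        assert res.thermo.dG_total == pytest.approx(8.0, rel=1e-3)


class TestGlobalSharedM:
    def test_single_curve_reduces_to_plain_fit(self, two_state_truth, baselines):
        c = simulate_two_state_curve(two_state_truth, baselines,
                                     noise=NoiseModel(0.02, 77))
        single = fit_two_state(c)
        g = fit_global_shared_m([c])
        assert g.shared_m == pytest.approx(single.thermo.m, rel=1e-8)
        assert g.per_curve[0].dG_app == pytest.approx(single.thermo.dG0, rel=1e-8)

    def test_five_curve_common_m_recovery(self, baselines):
        curves = [simulate_two_state_curve(ThermoTwoState(dG0=dg, m=4.8),
                                           baselines, noise=NoiseModel(0.01, i),
                                           mutant_id=str(i))
                  for i, dg in enumerate([6, 8, 10, 12, 14])]
        g = fit_global_shared_m(curves)
        assert g.shared_m == pytest.approx(4.8, rel=0.01)
        for p, dg in zip(g.per_curve, [6, 8, 10, 12, 14]):
            assert p.Cm * g.shared_m == pytest.approx(p.dG_app, rel=1e-10)
            assert p.dG_app == pytest.approx(dg, rel=0.05)

    def test_shared_m_lies_between_disparate_true_values(self, baselines):
        ca = simulate_two_state_curve(ThermoTwoState(dG0=6, m=2), baselines,
                                      noise=NoiseModel(0.01, 1), mutant_id="a")
        cb = simulate_two_state_curve(ThermoTwoState(dG0=12, m=6), baselines,
                                      noise=NoiseModel(0.01, 2), mutant_id="b")
        g = fit_global_shared_m([ca, cb])
        assert 2.0 < g.shared_m < 6.0

    def test_shared_m_cannot_beat_unconstrained_fits(self, baselines):
        curves = [simulate_two_state_curve(ThermoTwoState(dG0=dg, m=m), baselines,
                                           noise=NoiseModel(0.02, 40 + i),
                                           mutant_id=str(i))
                  for i, (dg, m) in enumerate([(6, 2.0), (9, 3.0), (12, 4.0)])]
        g = fit_global_shared_m(curves)
        free = sum(fit_two_state(c).residual_sum for c in curves)
        assert g.residual_sum >= free - 1e-10


class TestModelSelection:
    def test_two_state_data_selects_two_state(self, two_state_truth, baselines):
        c = simulate_two_state_curve(two_state_truth, baselines,
                                     noise=NoiseModel(0.01, 3))
        assert select_model(c).model == "two_state"

    def test_strong_intermediate_selects_three_state(self, three_state_truth,
                                                     baselines3):
        c = simulate_three_state_curve(three_state_truth, baselines3,
                                       noise=NoiseModel(0.01, 4))
        sel = select_model(c)
        assert sel.model == "three_state"
        assert sel.three_state.max_intermediate_population > 0.5

    def test_weak_intermediate_kept_two_state_by_population_floor(self, baselines3):
        # inverted midpoints suppress the intermediate (peak f_I ~ 0.07)
        weak = ThermoThreeState(dG1=8.05, m1=2.3, dG2=5.25, m2=2.1)
        c = simulate_three_state_curve(weak, baselines3, noise=NoiseModel(0.01, 6))
        sel = select_model(c, population_floor=0.20)
        pops = (sel.three_state.max_intermediate_population
                if sel.three_state else 0.0)
        assert sel.model == "two_state" or pops < 0.20


class TestHysteresis:
    def test_identical_arms_are_reversible(self, two_state_truth, baselines):
        f = simulate_two_state_curve(two_state_truth, baselines, arm="folding")
        u = TitrationCurve("x", f.denaturant, f.signal, arm="unfolding")
        rep = assess_hysteresis(f, u)
        assert rep.delta_Cm == pytest.approx(0.0, abs=1e-9)
        assert rep.max_fraction_gap == pytest.approx(0.0, abs=1e-9)
        assert rep.reversible

    def test_shifted_unfolding_arm_flags_irreversibility(self, baselines):
        f = simulate_two_state_curve(ThermoTwoState(dG0=8, m=2.5), baselines,
                                     noise=NoiseModel(0.01, 3), arm="folding")
        u = simulate_two_state_curve(ThermoTwoState(dG0=10.5, m=2.5), baselines,
                                     noise=NoiseModel(0.01, 4), arm="unfolding")
        rep = assess_hysteresis(f, u)
        assert rep.delta_Cm == pytest.approx(1.0, abs=0.1)
        assert not rep.reversible

    def test_baseline_only_offset_remains_reversible(self, two_state_truth,
                                                     baselines):
        f = simulate_two_state_curve(two_state_truth, baselines, arm="folding")
        u = TitrationCurve("x", f.denaturant, f.signal + 0.3, arm="unfolding")
        rep = assess_hysteresis(f, u)
        assert rep.reversible

    def test_disjoint_ranges_raise(self, two_state_truth, baselines):
        f = simulate_two_state_curve(two_state_truth, baselines,
                                     grid=default_grid(0.7, 3.0, 0.1))
        u = simulate_two_state_curve(two_state_truth, baselines,
                                     grid=default_grid(3.5, 6.6, 0.1))
        with pytest.raises((NoOverlap, NoTransition)):
            assess_hysteresis(f, u)
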