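"""Partitioning scales, ASA regressions, and scale correlations."""

import numpy as np
import pytest

from foldscale.energetics import (
    ASATable,
    PartitioningScale,
    ReferenceScale,
    atomic_solvation_parameter,
    build_partitioning_scale,
    conditional_scale_correlation,
    linear_correlation,
    load_asa_table,
    load_reference_scale,
    packaged_scale_names,
)
from foldscale.exceptions import (
    DegenerateX,
    InsufficientData,
    MissingReference,
    SelectorMismatch,
)
from foldscale.fitting import FitResult
from foldscale.models import Baselines, ThermoThreeState, ThermoTwoState


def _fit(res, dG, model="two_state", thermo=None):
    if thermo is None:
        thermo = ThermoTwoState(dG0=dG, m=2.5)
    return FitResult(mutant_id=res, model=model, thermo=thermo,
                     baselines=Baselines(1, -0.02, 0.35, -0.01),
                     param_errors={}, residual_sum=0.0, n_points=60, aicc=0.0)


class TestPartitioningScale:
    def test_reference_maps_to_zero_and_signs(self):
        fits = {"A": _fit("A", 5.0), "X": _fit("X", 3.0), "Y": _fit("Y", 7.0)}
        ps = build_partitioning_scale(fits, "phi")
        assert ps.values["A"] == 0.0
        assert ps.values["X"] == pytest.approx(2.0)   # less stabilizing
        assert ps.values["Y"] == pytest.approx(-2.0)  # more stabilizing

    def test_gauge_invariance_under_additive_shift(self):
        fits = {r: _fit(r, g) for r, g in [("A", 5.0), ("L", 9.0), ("G", 4.0)]}
        shifted = {r: _fit(r, g + 3.3) for r, g in [("A", 5.0), ("L", 9.0),
                                                    ("G", 4.0)]}
        a = build_partitioning_scale(fits, "phi").values
        b = build_partitioning_scale(shifted, "phi").values
        assert all(a[r] == pytest.approx(b[r], abs=1e-12) for r in a)

    def test_missing_reference_raises(self):
        with pytest.raises(MissingReference):
            build_partitioning_scale({"X": _fit("X", 3.0)}, "phi")

    def test_selector_mismatch_for_two_state_fit(self):
        fits = {"A": _fit("A", 5.0), "X": _fit("X", 3.0)}
        with pytest.raises(SelectorMismatch):
            build_partitioning_scale(fits, "pi", dg_selector="U_to_I")

    def test_auto_selector_uses_u_to_i_for_three_state(self):
        t3 = ThermoThreeState(dG1=3.0, m1=1.5, dG2=5.0, m2=1.2)  # U->I is dG2
        fits = {"A": _fit("A", 5.0),
                "W": _fit("W", None, model="three_state", thermo=t3)}
        ps = build_partitioning_scale(fits, "pi", dg_selector="auto")
        assert ps.values["W"] == pytest.approx(5.0 - 5.0)
        assert ps.provenance["W"] == "dG_U_to_I"
        total = build_partitioning_scale(fits, "pi", dg_selector="U_to_N_total")
        assert total.values["W"] == pytest.approx(5.0 - 8.0)


class TestLinearCorrelation:
    def test_exact_line_oracle(self):
        x = {r: float(i) for i, r in enumerate("ACDEF")}
        y = {r: 2.0 * v + 1.0 for r, v in x.items()}
        reg = linear_correlation(x, y)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(1.0)
        assert reg.r == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = {r: float(i) for i, r in enumerate("ACD")}
        y = {r: -v for r, v in x.items()}
        assert linear_correlation(x, y).r == pytest.approx(-1.0)

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(0)
        keys = list("ACDEFG")
        x = {k: float(v) for k, v in zip(keys, rng.normal(0, 2, 6))}
        y = {k: float(v) for k, v in zip(keys, rng.normal(1, 3, 6))}
        reg = linear_correlation(x, y)
        # independent closed-form oracle
        xv = np.array([x[k] for k in sorted(keys)])
        yv = np.array([y[k] for k in sorted(keys)])
        n = 6
        sxx = (xv * xv).sum() - xv.sum() ** 2 / n
        sxy = (xv * yv).sum() - xv.sum() * yv.sum() / n
        syy = (yv * yv).sum() - yv.sum() ** 2 / n
        assert reg.slope == pytest.approx(sxy / sxx, rel=1e-10)
        assert reg.intercept == pytest.approx(
            yv.mean() - sxy / sxx * xv.mean(), rel=1e-10)
        assert reg.r == pytest.approx(sxy / np.sqrt(sxx * syy), rel=1e-10)

    def test_insufficient_or_degenerate_inputs_raise(self):
        x = {"A": 1.0, "C": 2.0}
        with pytest.raises(InsufficientData):
            linear_correlation(x, x)
        flat = {"A": 1.0, "C": 1.0, "D": 1.0}
        with pytest.raises(DegenerateX):
            linear_correlation(flat, {"A": 1.0, "C": 2.0, "D": 3.0})


class TestASP:
    def _scale_on_line(self, asa, slope, residues):
        vals = {r: slope * (asa.delta_nonpolar[r] - asa.delta_nonpolar["A"])
                for r in residues}
        vals["A"] = 0.0
        return PartitioningScale("phi", "A", vals)

    def test_constructed_asp_recovered_exactly(self):
        from foldscale.simulate import synthetic_asa_table
        asa = synthetic_asa_table()
        residues = sorted(asa.delta_nonpolar)[:17]
        ps = self._scale_on_line(asa, 0.043, residues)
        reg = atomic_solvation_parameter(ps, asa, "nonpolar")
        assert reg.slope == pytest.approx(0.043, rel=1e-10)
        assert reg.r == pytest.approx(1.0)

    def test_excluded_outlier_does_not_move_slope(self):
        from foldscale.simulate import synthetic_asa_table
        asa = synthetic_asa_table()
        residues = sorted(asa.delta_nonpolar)
        ps = self._scale_on_line(asa, 0.043, residues)
        vals = dict(ps.values)
        vals["W"] = 25.0  # gross outlier
        ps_out = PartitioningScale("phi", "A", vals)
        reg = atomic_solvation_parameter(ps_out, asa, "nonpolar", excluded=["W"])
        assert reg.slope == pytest.approx(0.043, rel=1e-10)
        assert "W" in reg.excluded

    def test_sign_flip_of_scale_flips_asp(self):
        from foldscale.simulate import synthetic_asa_table
        asa = synthetic_asa_table()
        residues = sorted(asa.delta_nonpolar)
        ps = self._scale_on_line(asa, 0.043, residues)
        neg = PartitioningScale("pi", "A", {r: -v for r, v in ps.values.items()})
        assert atomic_solvation_parameter(neg, asa, "nonpolar").slope \
            == pytest.approx(-0.043, rel=1e-10)

    def test_deletion_variants_are_auto_excluded(self):
        from foldscale.simulate import synthetic_asa_table
        asa = synthetic_asa_table()
        residues = sorted(asa.delta_nonpolar)
        vals = self._scale_on_line(asa, 0.043, residues).values
        vals = dict(vals); vals["dF"] = 9.9   # deletion variant, no side chain
        ps = PartitioningScale("phi", "A", vals)
        reg = atomic_solvation_parameter(ps, asa, "nonpolar")
        assert "dF" in reg.excluded
        assert reg.slope == pytest.approx(0.043, rel=1e-10)


class TestConditionalCorrelation:
    def test_single_line_gives_identical_slopes(self):
        vals = {r: 0.3 * i + 0.1 for i, r in enumerate("ACDEFGHIKL")}
        ps = PartitioningScale("phi", "A", {**{r: v - vals["A"] for r, v in
                                               vals.items()}, "A": 0.0})
        ref = ReferenceScale("toy", {r: float(i) for i, r in
                                     enumerate("ACDEFGHIKL")})
        a, b = conditional_scale_correlation(ps, ref, list("ACDEF"),
                                             list("GHIKL"))
        assert a.slope == pytest.approx(b.slope, rel=1e-9)

    def test_two_line_construction_recovers_both_slopes(self):
        # hydrophobic subset on slope 0.2, hydrophilic on slope 0.5
        hydroph = list("ILVFM")
        polar = list("STNQK")
        ref_vals = {r: float(i) for i, r in enumerate(hydroph + polar)}
        vals = {r: 0.2 * ref_vals[r] for r in hydroph}
        vals.update({r: 0.5 * ref_vals[r] - 1.0 for r in polar})
        vals["A"] = 0.0
        ps = PartitioningScale("phi", "A", vals)
        ref = ReferenceScale("toy", ref_vals)
        a, b = conditional_scale_correlation(ps, ref, hydroph, polar)
        assert a.slope == pytest.approx(0.2, rel=1e-9)
        assert b.slope == pytest.approx(0.5, rel=1e-9)

    def test_overlapping_subsets_are_allowed(self):
        vals = {r: 1.0 * i for i, r in enumerate("ACDEF")}
        vals["A"] = 0.0
        ps = PartitioningScale("phi", "A", vals)
        ref = ReferenceScale("toy", {r: float(i) for i, r in enumerate("ACDEF")})
        a, b = conditional_scale_correlation(ps, ref, list("ACD"), list("CDE"))
        assert a.n_used == 3 and b.n_used == 3


class TestPackagedTables:
    def test_packaged_asa_table_covers_standard_residues(self):
        asa = load_asa_table()
        assert set(asa.delta_nonpolar) == set("ACDEFGHIKLMNPQRSTVWY")
        assert all(np.isfinite(v) for v in asa.delta_nonpolar.values())

    def test_packaged_scales_load(self):
        names = packaged_scale_names()
        assert "wimley_white_interface" in names
        for name in names:
            sc = load_reference_scale(name)
            assert set(sc.values) == set("ACDEFGHIKLMNPQRSTVWY")
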