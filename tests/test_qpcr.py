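"""Standard curves, normalization modes, reference screen, group tests."""

import itertools
import math

import numpy as np
import pytest

from srebscan.qpcr import (
    CtRecord,
    RelExpression,
    StandardCurve,
    compact_letter_display,
    fit_standard_curve,
    group_tests,
    quantify,
    quantity_from_ct,
    reference_gene_screen,
    relative_expression,
)
from srebscan.simulate import QpcrConfig, SimConfig, simulate_ct

from conftest import small_config


def perfect_series(slope=-3.321928, intercept=24.0, points=5):
    return [(10.0 ** -k, intercept + slope * -k) for k in range(points)]


def ct_records_from_rows(rows):
    grouped = {}
    for r in rows:
        grouped.setdefault((r.sample_id, r.group, r.gene), []).append(r)
    return [
        CtRecord(s, g, gene, tuple(x.ct for x in xs), xs[0].input_rna_ug)
        for (s, g, gene), xs in grouped.items()
    ]


def simulated_qpcr(seed=0, **qpcr_overrides):
    qp = QpcrConfig(**qpcr_overrides)
    cfg = small_config(seed, qpcr=qp)
    rows, dilutions, truth = simulate_ct(cfg)
    records = ct_records_from_rows(rows)
    curves = {g: fit_standard_curve(d, g) for g, d in dilutions.items()}
    return records, curves, truth


class TestStandardCurve:
    def test_perfect_doubling_slope_gives_100pct(self):
        curve = fit_standard_curve(perfect_series(slope=-3.321928))
        assert round(curve.slope, 4) == -3.3219
        assert curve.efficiency * 100 == pytest.approx(100.0, abs=5e-3)
        assert curve.qc_pass

    def test_ninety_pct_efficiency_passes_qc(self):
        # 10^(-1/s) = 1.9  =>  s = -1/log10(1.9)
        slope = -1.0 / math.log10(1.9)
        curve = fit_standard_curve(perfect_series(slope=slope))
        assert curve.efficiency * 100 == pytest.approx(90.0, abs=5e-2)
        assert curve.qc_pass

    def test_out_of_window_efficiency_fails_qc(self):
        slope = -1.0 / math.log10(1.5)  # 50% efficiency
        curve = fit_standard_curve(perfect_series(slope=slope))
        assert not curve.qc_pass

    def test_noiseless_series_r_squared_one(self):
        curve = fit_standard_curve(perfect_series())
        assert curve.r_squared == pytest.approx(1.0)

    def test_fewer_than_four_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_standard_curve(perfect_series(points=3))

    def test_non_monotone_series_warns(self):
        pts = perfect_series()
        pts[2] = (pts[2][0], pts[0][1] - 5.0)
        with pytest.warns(UserWarning, match="non-monotone"):
            curve = fit_standard_curve(pts)
        assert "non-monotone" in curve.qc_note

    def test_replicates_averaged_before_fit(self):
        pts = perfect_series()
        jittered = [(q, ct + d) for q, ct in pts for d in (-0.3, 0.3)]
        curve = fit_standard_curve(jittered)
        assert curve.r_squared == pytest.approx(1.0)


class TestQuantify:
    def curve(self):
        return fit_standard_curve(perfect_series())

    def test_equal_cts_give_unity_in_ref_mode(self):
        c = self.curve()
        t = CtRecord("s1", "G", "sreb2", (24.0,))
        r = CtRecord("s1", "G", "18s", (24.0,))
        v = quantify(t, c, "ref_gene", ref=r, ref_curve=c)
        assert v.value == pytest.approx(1.0)

    def test_per_ug_input_scales_inversely_with_input(self):
        c = self.curve()
        a = quantify(CtRecord("s1", "G", "g", (24.0,), 1.0), c, "per_ug_input")
        b = quantify(CtRecord("s2", "G", "g", (24.0,), 2.0), c, "per_ug_input")
        assert a.value / b.value == pytest.approx(2.0)

    def test_fixed_input_rejects_unequal_inputs(self):
        c = self.curve()
        rec = CtRecord("s1", "G", "g", (24.0,), 1.0)
        with pytest.raises(ValueError, match="differs"):
            quantify(rec, c, "fixed_input", fixed_input_ug=2.5)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            quantify(CtRecord("s", "G", "g", (24.0,)), self.curve(), "ref_gene")

    def test_ct_validation(self):
        with pytest.raises(ValueError):
            CtRecord("s", "G", "g", ())
        with pytest.raises(ValueError):
            CtRecord("s", "G", "g", (0.0,))


class TestPlantedFoldChanges:
    def test_noiseless_recovery_to_1e_minus_9(self):
        records, curves, truth = simulated_qpcr(
            seed=1, ct_sd=0.0,
            planted_fold_changes={("sreb2", "TR"): 8.0, ("sreb2", "OVV"): 0.25},
        )
        vals = relative_expression(records, curves, "ref_gene", "TS",
                                   reference_gene="18s")
        for group, want in (("TR", 8.0), ("OVV", 0.25)):
            got = np.mean([v.value for v in vals
                           if v.gene == "sreb2" and v.group == group])
            assert abs(got - want) / want <= 1e-9

    def test_eight_fold_is_three_cycles(self):
        rows, _, _ = simulate_ct(small_config(0, qpcr=QpcrConfig(
            ct_sd=0.0, planted_fold_changes={("sreb2", "TR"): 8.0},
        )))
        cts = {}
        for r in rows:
            if r.gene == "sreb2":
                cts.setdefault(r.group, set()).add(round(r.ct, 9))
        assert len(cts["TS"]) == len(cts["TR"]) == 1
        assert cts["TS"].pop() - cts["TR"].pop() == pytest.approx(3.0)

    def test_scale_invariance_of_ref_mode(self):
        records, curves, _ = simulated_qpcr(
            seed=2, ct_sd=0.0, planted_fold_changes={("sreb2", "TR"): 4.0},
        )
        vals = relative_expression(records, curves, "ref_gene", "TS",
                                   reference_gene="18s")
        # shift every Ct by a constant: all quantities scale by one factor
        shifted = [
            CtRecord(r.sample_id, r.group, r.gene,
                     tuple(c - 1.0 for c in r.cts), r.input_rna_ug)
            for r in records
        ]
        vals2 = relative_expression(shifted, curves, "ref_gene", "TS",
                                    reference_gene="18s")
        for v1, v2 in zip(vals, vals2):
            assert v1.value == pytest.approx(v2.value, rel=1e-9)

    def test_fixed_vs_per_ug_proportional_at_constant_input(self):
        records, curves, _ = simulated_qpcr(
            seed=3, ct_sd=0.0, input_rna_ug=2.5,
            planted_fold_changes={("sreb3b", "OVV"): 0.5},
        )
        fixed = relative_expression(records, curves, "fixed_input", "TS")
        perug = relative_expression(records, curves, "per_ug_input", "TS")
        # identical after calibrator scaling; pre-calibration ratio is 2.5
        for a, b in zip(fixed, perug):
            assert a.value == pytest.approx(b.value, rel=1e-9)
        q = quantity_from_ct(records[0].ct, curves[records[0].gene])
        assert q / (q / records[0].input_rna_ug) == pytest.approx(2.5)


class TestReferenceGeneScreen:
    def test_stable_and_unstable_candidates(self):
        records, curves, _ = simulated_qpcr(
            seed=4, ct_sd=0.1,
            planted_fold_changes={("gapdh", "OVV"): 5.0},
        )
        report = reference_gene_screen(records, ["18s", "gapdh"], curves)
        assert report["18s"][0] is True
        assert report["gapdh"][0] is False and report["gapdh"][1] < 0.05

    def test_pipeline_refuses_unstable_reference(self):
        records, curves, _ = simulated_qpcr(
            seed=5, ct_sd=0.1, planted_fold_changes={("gapdh", "OVV"): 5.0},
        )
        report = reference_gene_screen(records, ["gapdh"], curves)
        unstable = {g: p for g, (ok, p) in report.items() if not ok}
        with pytest.raises(ValueError, match="unstable"):
            relative_expression(records, curves, "ref_gene", "TS",
                                reference_gene="gapdh", unstable=unstable)

    def test_single_group_rejected(self):
        records, curves, _ = simulated_qpcr(seed=6)
        only_ts = [r for r in records if r.group == "TS"]
        with pytest.raises(ValueError, match="2 groups"):
            reference_gene_screen(only_ts, ["18s"], curves)


class TestGroupTests:
    @staticmethod
    def rel(group, values, gene="g"):
        return [
            RelExpression(f"{group}{i}", group, gene, v, "ref_gene", "TS")
            for i, v in enumerate(values)
        ]

    def test_identical_groups_share_letter(self):
        vals = self.rel("A", [1.0, 1.1, 0.9]) + self.rel("B", [1.0, 1.1, 0.9])
        gs = group_tests(vals)
        assert gs.p_value > 0.9
        assert gs.tukey_letters["A"] == gs.tukey_letters["B"]

    def test_planted_difference_significant(self):
        rng = np.random.default_rng(0)
        a = self.rel("A", np.exp(rng.normal(0, 0.1, 8)))
        b = self.rel("B", np.exp(rng.normal(np.log(8), 0.1, 8)))
        gs = group_tests(a + b)
        assert gs.test == "t_test" and gs.p_value < 0.05
        assert gs.tukey_letters["A"] != gs.tukey_letters["B"]

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(1)
        vals = (
            self.rel("A", np.exp(rng.normal(0, 0.1, 6)))
            + self.rel("B", np.exp(rng.normal(0, 0.1, 6)))
            + self.rel("C", np.exp(rng.normal(np.log(10), 0.1, 6)))
        )
        gs = group_tests(vals)
        assert gs.test == "anova" and gs.p_value < 0.05
        assert gs.tukey_letters["A"] == gs.tukey_letters["B"]
        assert gs.tukey_letters["C"] != gs.tukey_letters["A"]

    def test_nonpositive_values_rejected(self):
        vals = self.rel("A", [1.0, 0.0]) + self.rel("B", [1.0, 2.0])
        with pytest.raises(ValueError, match="positive"):
            group_tests(vals)

    def test_mixed_genes_rejected(self):
        vals = self.rel("A", [1.0, 2.0], "g1") + self.rel("B", [1.0, 2.0], "g2")
        with pytest.raises(ValueError, match="one gene"):
            group_tests(vals)


class TestCompactLetterDisplay:
    def test_valid_display_on_random_significance_patterns(self):
        groups = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(42)
        for _ in range(25):
            sig = {
                frozenset(p) for p in itertools.combinations(groups, 2)
                if rng.random() < 0.4
            }
            letters = compact_letter_display(groups, sig)
            for a, b in itertools.combinations(groups, 2):
                shared = set(letters[a]) & set(letters[b])
                if frozenset((a, b)) in sig:
                    assert not shared, (letters, a, b)
                else:
                    assert shared, (letters, a, b)
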