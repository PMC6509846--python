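"""Efficiency estimation, reference screening and Pfaffl quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pigmentpattern.qpcr import (efficiency_factors,
                                 efficiency_from_standard_curve,
                                 expression_table, percent_to_factor,
                                 pfaffl_ratio, screen_reference_genes,
                                 significance_stars)
from pigmentpattern.synth import (screen_design, simulate_qpcr,
                                  simulate_standard_curve)


class TestEfficiency:
    def test_perfect_doubling_slope(self):
        pts = [(d, 30 - 3.321928 * d) for d in (-4, -3, -2, -1, 0)]
        est = efficiency_from_standard_curve(pts)
        assert est.efficiency == pytest.approx(2.0, abs=1e-6)
        assert est.percent == pytest.approx(100.0, abs=1e-3)

    def test_generator_inversion_is_exact(self):
        est = efficiency_from_standard_curve(
            simulate_standard_curve(1.95, gene="dct"), gene="dct")
        assert est.percent == pytest.approx(95.0, abs=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            efficiency_from_standard_curve([(-1, 25.0), (0, 22.0)])

    def test_non_negative_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            efficiency_from_standard_curve([(-2, 20.0), (-1, 22.0), (0, 25.0)])

    def test_percent_and_factor_conversions(self):
        assert percent_to_factor(110.3) == pytest.approx(2.103)
        table = pd.DataFrame({"gene": ["dct"], "percent_efficiency": [110.3]})
        assert efficiency_factors(table) == {"dct": pytest.approx(2.103)}
        # mapping values may be factors or percents; scales do not overlap
        assert efficiency_factors({"a": 1.9, "b": 95.0}) == \
            {"a": 1.9, "b": pytest.approx(1.95)}


class TestPfafflRatio:
    REFS = {"rps20": {"BTB": 20.0, "MTD": 20.0},
            "pgk1": {"BTB": 21.0, "MTD": 21.0}}

    def test_reduces_to_ddcq_when_all_efficiencies_two(self):
        ratios = pfaffl_ratio({"BTB": 20.0, "MTD": 18.0}, self.REFS,
                              {"rps20": 2.0, "pgk1": 2.0, "target": 2.0},
                              "BTB")
        assert ratios["MTD"] == pytest.approx(4.0, abs=1e-12)
        assert ratios["BTB"] == pytest.approx(1.0, abs=1e-12)

    def test_target_equal_to_reference_is_self_normalized(self):
        ratios = pfaffl_ratio(self.REFS["rps20"], self.REFS,
                              {"rps20": 2.0, "pgk1": 2.0, "target": 2.0},
                              "BTB")
        assert all(r == pytest.approx(1.0, abs=1e-12) for r in ratios.values())

    def test_amplicon_specific_efficiency_applied(self):
        ratios = pfaffl_ratio({"BTB": 20.0, "MTD": 19.0}, self.REFS,
                              {"rps20": 2.0, "pgk1": 2.0, "target": 2.103},
                              "BTB")
        assert ratios["MTD"] == pytest.approx(2.103, abs=1e-12)

    def test_missing_reference_measurement_flags_nan(self):
        refs = {"rps20": {"BTB": 20.0, "MTD": 20.0}, "pgk1": {"BTB": 21.0}}
        with pytest.warns(UserWarning, match="missing reference"):
            ratios = pfaffl_ratio({"BTB": 20.0, "MTD": 18.0}, refs,
                                  {"rps20": 2.0, "pgk1": 2.0, "target": 2.0},
                                  "BTB")
        assert np.isnan(ratios["MTD"])

    def test_monotone_decreasing_in_target_cq(self):
        base = {"BTB": 20.0}
        vals = [pfaffl_ratio({**base, "MTD": cq}, self.REFS,
                             {"rps20": 2.0, "pgk1": 2.0, "target": 1.9},
                             "BTB")["MTD"] for cq in (17.0, 18.5, 20.0, 23.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @given(shift=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_reference_shift_invariance(self, shift):
        # adding a constant to one reference gene everywhere changes nothing
        shifted = {"rps20": {g: c + shift for g, c in self.REFS["rps20"].items()},
                   "pgk1": self.REFS["pgk1"]}
        eff = {"rps20": 1.98, "pgk1": 2.05, "target": 2.0}
        a = pfaffl_ratio({"BTB": 20.0, "MTD": 18.0}, self.REFS, eff, "BTB")
        b = pfaffl_ratio({"BTB": 20.0, "MTD": 18.0}, shifted, eff, "BTB")
        assert a["MTD"] == pytest.approx(b["MTD"], rel=1e-12)


class TestExpressionTable:
    def test_noiseless_offset_recovered_exactly_with_p_undefined(self):
        from _designs import two_region_design
        d = two_region_design(offset=-2.0, noise=0.0)
        cq, _ = simulate_qpcr(d, seed=0)
        tab = expression_table(cq, d.efficiencies, ("rps20", "pgk1"), "BTB")
        row = tab.summary.query("gene == 'tgt' and region == 'MTD'").iloc[0]
        assert row["log2_ratio_mean"] == pytest.approx(2.0, abs=1e-12)
        assert np.isnan(row["p"])  # zero variance: test undefined, flagged

    def test_calibrator_group_mean_is_zero(self):
        from pigmentpattern.synth import trout_design
        d = trout_design()
        cq, _ = simulate_qpcr(d, seed=3)
        tab = expression_table(cq, d.efficiencies, ("rps20", "pgk1"), "BTB")
        cal = tab.summary[tab.summary["region"] == "BTB"]
        assert np.allclose(cal["log2_ratio_mean"], 0.0, atol=1e-12)

    def test_reference_gene_cq_shift_leaves_ratios_unchanged(self):
        from pigmentpattern.synth import trout_design
        d = trout_design()
        cq, _ = simulate_qpcr(d, seed=3)
        shifted = cq.copy()
        shifted.loc[shifted["gene"] == "rps20", "cq"] += 3.7
        a = expression_table(cq, d.efficiencies, ("rps20", "pgk1"), "BTB")
        b = expression_table(shifted, d.efficiencies, ("rps20", "pgk1"), "BTB")
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_missing_reference_or_calibrator_rejected(self):
        from pigmentpattern.synth import trout_design
        d = trout_design()
        cq, _ = simulate_qpcr(d, seed=0)
        with pytest.raises(ValueError, match="reference"):
            expression_table(cq, d.efficiencies, ("rps20", "nope"), "BTB")
        with pytest.raises(ValueError, match="calibrator"):
            expression_table(cq, d.efficiencies, ("rps20", "pgk1"), "XXX")

    def test_small_group_reported_without_test(self):
        from _designs import two_region_design
        d = two_region_design(offset=-1.0, noise=0.1, n=1)
        cq, _ = simulate_qpcr(d, seed=0)
        tab = expression_table(cq, d.efficiencies, ("rps20", "pgk1"), "BTB")
        row = tab.summary.query("gene == 'tgt' and region == 'MTD'").iloc[0]
        assert np.isfinite(row["log2_ratio_mean"])
        assert np.isnan(row["p"])


class TestReferenceScreen:
    def test_zero_variance_candidate_ranks_first(self):
        rows = []
        for i in range(6):
            for gene, cqv in (("flat", 20.0), ("wobbly", 20.0 + i)):
                rows.append({"individual": f"f{i}", "region": "R1",
                             "gene": gene, "replicate": 1, "cq": cqv})
        ranked = screen_reference_genes(pd.DataFrame(rows), ["wobbly", "flat"])
        assert ranked.iloc[0]["gene"] == "flat"
        assert ranked.iloc[0]["stability_sd"] == 0.0

    def test_stable_pair_found_in_synthetic_panel(self):
        d = screen_design()
        cq, _ = simulate_qpcr(d, seed=9)
        ranked = screen_reference_genes(cq, d.genes)
        assert set(ranked[ranked["chosen"]]["gene"]) == {"rps20", "pgk1"}

    def test_candidate_with_missing_samples_excluded(self):
        d = screen_design()
        cq, _ = simulate_qpcr(d, seed=1)
        cq = cq[~((cq["gene"] == "sdha") & (cq["region"] == "MTD"))]
        with pytest.warns(UserWarning, match="sdha"):
            ranked = screen_reference_genes(cq, d.genes)
        assert "sdha" not in set(ranked["gene"])

    def test_single_candidate_warns(self):
        rows = [{"individual": "f1", "region": "R1", "gene": "only",
                 "replicate": r, "cq": 20.0} for r in (1, 2)]
        rows += [{"individual": "f2", "region": "R1", "gene": "only",
                  "replicate": r, "cq": 20.1} for r in (1, 2)]
        with pytest.warns(UserWarning, match="two are required"):
            ranked = screen_reference_genes(pd.DataFrame(rows), ["only"])
        assert len(ranked) == 1


def test_significance_stars_thresholds():
    assert [significance_stars(p) for p in (0.2, 0.04, 0.009, 0.0009,
                                            float("nan"))] == \
        ["", "*", "**", "***", ""]
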