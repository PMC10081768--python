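"""Stage binning, hierarchical aggregation, tests and Gad arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from myoslip.stats import (
    GadCount,
    StageBinning,
    aggregate,
    bin_stage,
    gad_stats,
    paired_t,
    stage_report,
    superplot_export,
    welch_t,
)


class TestBinStage:
    @pytest.mark.parametrize("t,expected", [
        (3.0, "early"), (7.0, "early"), (5.0, "early"),
        (13.0, "late"), (20.0, "late"),
        (2.9, "excluded"), (7.1, "excluded"), (10.0, "excluded"), (12.99, "excluded"),
    ])
    def test_boundaries(self, t, expected):
        assert bin_stage(t) == expected

    def test_total_function_and_disjoint_windows(self):
        for t in np.linspace(-5, 30, 701):
            assert bin_stage(t) in ("early", "late", "excluded")

    def test_invalid_binning_rejected(self):
        with pytest.raises(ValueError):
            StageBinning(early_lo=3, early_hi=14, late_lo=13)

    def test_nonfinite_time_rejected(self):
        with pytest.raises(ValueError):
            bin_stage(float("nan"))


def _nested_records(rng=None):
    """3 embryos x 2 cells x 4 legs per stage, known values."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for e in range(3):
        for c in (1, 2):
            for leg in range(4):
                for stage, base in (("early", 1.5), ("late", 0.8)):
                    rows.append({
                        "embryo": f"e{e}", "cell": c, "leg": leg, "stage": stage,
                        "v_myo": base + 0.3 + 0.01 * e, "v_mem": 0.3,
                        "slippage": base + 0.01 * e + 0.001 * c + 0.0001 * leg,
                        "flag": "",
                    })
    return pd.DataFrame(rows)


class TestAggregate:
    def test_single_record_propagates_to_all_levels(self):
        df = pd.DataFrame([{"embryo": "e", "cell": 1, "stage": "early",
                            "v_myo": 1.5, "v_mem": 0.0, "slippage": 1.5, "flag": ""}])
        agg = aggregate(df)
        assert agg["cell"]["slippage"].iloc[0] == 1.5
        assert agg["embryo"]["slippage"].iloc[0] == 1.5
        assert agg["condition"]["slippage"].iloc[0] == 1.5

    def test_two_legs_average_within_cell(self):
        df = pd.DataFrame([
            {"embryo": "e", "cell": 1, "stage": "early", "v_myo": 1, "v_mem": 0,
             "slippage": 1.0, "flag": ""},
            {"embryo": "e", "cell": 1, "stage": "early", "v_myo": 2, "v_mem": 0,
             "slippage": 2.0, "flag": ""},
        ])
        assert aggregate(df)["cell"]["slippage"].iloc[0] == pytest.approx(1.5)

    def test_condition_mean_equals_brute_force_grand_mean_of_embryo_means(self):
        df = _nested_records()
        agg = aggregate(df)
        for stage in ("early", "late"):
            sub = df[df.stage == stage]
            emb_means = []
            for e, edf in sub.groupby("embryo"):
                cell_means = [cdf["slippage"].mean() for _, cdf in edf.groupby("cell")]
                emb_means.append(np.mean(cell_means))
            got = agg["condition"]
            got = got[got.stage == stage]["slippage"].iloc[0]
            assert got == pytest.approx(np.mean(emb_means))

    def test_permutation_invariance(self):
        df = _nested_records()
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = aggregate(df)["condition"].sort_values(["condition", "stage"]).reset_index(drop=True)
        b = aggregate(shuffled)["condition"].sort_values(["condition", "stage"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_flagged_and_excluded_dropped_empty_group_missing(self):
        df = pd.DataFrame([
            {"embryo": "e", "cell": 1, "stage": "early", "v_myo": 1, "v_mem": 0,
             "slippage": 1.0, "flag": "no-flow"},
            {"embryo": "e", "cell": 1, "stage": "excluded", "v_myo": 1, "v_mem": 0,
             "slippage": 1.0, "flag": ""},
        ])
        agg = aggregate(df)
        assert agg["condition"].empty


class TestWelchT:
    def test_identical_groups(self):
        t, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_matches_reference_to_6_decimals(self):
        a, b = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        t, p = welch_t(a, b)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(t_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_matches_reference_on_unequal_sizes_and_variances(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 7)
        b = rng.normal(1, 3, 13)
        t, p = welch_t(a, b)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(t_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_p_decreases_with_separation(self):
        base = np.array([0.0, 0.5, 1.0, 1.5])
        ps = [welch_t(base, base + d)[1] for d in (0.5, 1.0, 2.0, 4.0)]
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            welch_t([2, 2, 2], [3, 3, 3])


class TestPairedT:
    def test_zero_differences(self):
        t, p = paired_t([(1, 1), (2, 2), (3, 3)])
        assert t == 0.0 and p == 1.0

    def test_matches_reference(self):
        pairs = [(1.5, 0.8), (1.6, 0.8), (1.55, 0.8)]  # diffs 0.7, 0.8, 0.75
        t, p = paired_t(pairs)
        a, b = zip(*pairs)
        t_ref, p_ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(t_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_sign_flip_negates_statistic_keeps_p(self):
        pairs = [(1.0, 0.2), (1.4, 0.9), (1.2, 0.5), (0.8, 0.4)]
        t1, p1 = paired_t(pairs)
        t2, p2 = paired_t([(b, a) for a, b in pairs])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_incomplete_pairs_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="incomplete"):
            t, p = paired_t([(1, 0.5), (2, 1.0), (np.nan, 1.0), (3, 1.5)])
        t_ref, _ = sps.ttest_rel([1, 2, 3], [0.5, 1.0, 1.5])
        assert t == pytest.approx(t_ref, abs=1e-9)


# "% Gad" percentages recomputed (round-half-up, 1 decimal) from scored counts
TABLE1_CELLS = [
    ("Negative Control", 0, 20, 0.0),
    ("mlt-2", 3, 14, 21.4),
    ("afd-1", 5, 20, 25.0),
    ("gei-4", 5, 12, 41.7),
    ("inx-3", 0, 12, 0.0),
    ("noah-1", 4, 13, 30.8),
    ("Y38H6C.14", 5, 17, 29.4),
    ("acp-2", 2, 16, 12.5),
    ("add-1", 1, 13, 7.7),
    ("C29F7.2", 3, 11, 27.3),
    ("C46E10.8", 6, 12, 50.0),
    ("ctn-1", 2, 10, 20.0),
    ("grdn-1", 3, 9, 33.3),
    ("H24G06.1", 2, 14, 14.3),
    ("hum-8", 6, 9, 66.7),
    ("pssy-1", 1, 14, 7.1),
    ("R06B10.2", 5, 7, 71.4),
    ("T14E8.1", 2, 12, 16.7),
    ("Y57G11C.6", 3, 10, 30.0),
    ("zig-5", 5, 16, 31.3),
    ("zyx-1", 5, 20, 25.0),
    ("zyx-1 ko", 19, 46, 41.3),
]


class TestGadStats:
    @pytest.mark.parametrize("label,n,total,pct", TABLE1_CELLS)
    def test_percentages_from_counts(self, label, n, total, pct):
        assert GadCount(label, n, total).percent == pct

    def test_goodness_of_fit_matches_scipy(self):
        counts = [GadCount("exp", 2, 27), GadCount("ref", 19, 46)]
        out = gad_stats(counts, [("exp", "ref")])
        p_exp = 19 / 46
        chi2_ref, p_ref = sps.chisquare([2, 25], f_exp=[27 * p_exp, 27 * (1 - p_exp)])
        row = out["comparisons"].iloc[0]
        assert row["chi2"] == pytest.approx(chi2_ref)
        assert row["p"] == pytest.approx(p_ref)

    def test_contingency_variant(self):
        counts = [GadCount("a", 5, 20), GadCount("b", 19, 46)]
        out = gad_stats(counts, [("a", "b")], method="contingency")
        chi2_ref, p_ref, _, _ = sps.chi2_contingency([[5, 15], [19, 27]], correction=False)
        row = out["comparisons"].iloc[0]
        assert row["chi2"] == pytest.approx(chi2_ref)
        assert row["p"] == pytest.approx(p_ref)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            GadCount("x", 1, 0)
        with pytest.raises(ValueError):
            GadCount("x", 5, 4)


class TestReportAndSuperplot:
    def test_stage_report_shape_and_difference(self):
        rep = stage_report(_nested_records())
        slip = rep[rep.measurement == "Slippage"].iloc[0]
        assert slip["mean_difference"] == pytest.approx(
            slip["mean_early"] - slip["mean_late"])
        assert slip["n_early"] == 3 and slip["n_late"] == 3
        assert 0 <= slip["p_early_vs_late"] <= 1

    def test_report_control_comparisons(self):
        df = _nested_records()
        df2 = _nested_records()
        df["condition"] = "control"
        df2["condition"] = "mutant"
        df2["slippage"] += 0.5
        rep = stage_report(pd.concat([df, df2], ignore_index=True), control="control")
        mut = rep[(rep.condition == "mutant") & (rep.measurement == "Slippage")].iloc[0]
        assert 0 <= mut["p_early_vs_control"] <= 1

    def test_superplot_schema_and_counts(self, tmp_path):
        df = _nested_records()
        table = superplot_export(df, tmp_path / "sp.csv")
        n_leg = len(df)
        n_rep = 3 * 2  # embryos x stages
        n_cond = 2  # stages
        assert len(table) == n_leg + n_rep + n_cond
        cond_rows = table[table.level == "condition"]
        agg = aggregate(df)["condition"]
        for _, row in cond_rows.iterrows():
            expect = agg[agg.stage == row["stage"]]["slippage"].iloc[0]
            assert row["slippage"] == pytest.approx(expect)

    def test_superplot_rerun_byte_identical(self, tmp_path):
        df = _nested_records()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        superplot_export(df, p1)
        superplot_export(df.sample(frac=1.0, random_state=1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_superplot_figure_written(self, tmp_path):
        superplot_export(_nested_records(), tmp_path / "sp.csv", tmp_path / "sp.png")
        assert (tmp_path / "sp.png").stat().st_size > 0
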