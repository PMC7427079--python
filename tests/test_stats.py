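"""Cohort statistics: means with CI, Spearman, Wilcoxon, summary tables."""

import numpy as np
import pandas as pd
import pytest

import ctdikit as ck
from ctdikit.metrics import SegmentSummary
from ctdikit.stats import (
    DegenerateDataError,
    InsufficientDataError,
    build_tables,
    outlier_audit,
)


class TestMeanZWithCI:
    def test_constant_values_degenerate_ci(self):
        r = ck.mean_z_with_ci([0.5, 0.5, 0.5, 0.5])
        assert r.estimate == 0.5
        assert r.interval == (0.5, 0.5)
        assert r.significant

    def test_symmetric_values_not_significant(self):
        r = ck.mean_z_with_ci([-1.0, -0.5, 0.5, 1.0])
        assert r.estimate == pytest.approx(0.0)
        assert not r.significant

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            ck.mean_z_with_ci([0.1, 0.2])

    def test_coverage_and_power(self):
        """CI covers the true mean ~95% of the time and excludes 0 for a
        clear shift at large n."""
        rng = np.random.default_rng(1)
        cover = signif = 0
        reps = 120
        for _ in range(reps):
            x = rng.normal(0.4, 1.0, 200)
            r = ck.mean_z_with_ci(x)
            cover += r.interval[0] <= 0.4 <= r.interval[1]
            signif += r.significant
        assert cover / reps >= 0.88
        assert signif / reps >= 0.95


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert ck.spearman_corr(x, np.exp(x)).estimate == pytest.approx(1.0)
        assert ck.spearman_corr(x, -(x**3)).estimate == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            ck.spearman_corr(np.ones(10), np.arange(10.0))

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            ck.spearman_corr([1, 2, 3], [3, 2, 1])


class TestPairedWilcoxon:
    def test_unit_shift_on_twenty_pairs(self):
        before = np.linspace(1, 5, 20)
        r = ck.paired_wilcoxon(before, before - 1.0)
        assert r.p_value < 0.01
        assert r.estimate == pytest.approx(-1.0)

    def test_identical_pairs_degenerate(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateDataError):
            ck.paired_wilcoxon(x, x)

    def test_too_few_nonzero_differences(self):
        b = np.zeros(6)
        a = np.array([0, 0, 0.1, 0, 0, -0.2])
        with pytest.raises(InsufficientDataError):
            ck.paired_wilcoxon(b, a)


def _tiny_cohort(ref):
    """Six fetuses, LV only, hand-set values at fixed GA."""
    ga = 28.0
    records, summaries = [], []
    values_before = [4.0, 4.5, 5.0, 5.5, 6.0, 6.5]  # Am means, cm/s
    values_after = [v - 1.0 for v in values_before]
    for i, (vb, va) in enumerate(zip(values_before, values_after)):
        fid = f"T{i}"
        for timing, v in (("before", vb), ("after", va)):
            rec = ck.ExamRecord(fid, 1, timing, ga, hb_g_per_L=100.0, mca_psv_cm_per_s=40.0)
            records.append(rec)
            summaries.append(
                SegmentSummary(
                    exam_id=rec.exam_id,
                    wall="LV",
                    sm_mean=3.0,
                    am_mean=v,
                    em_mean=3.5,
                    em_am_ratio=3.5 / v,
                    heart_rate=140.0,
                    n_beats_total=9,
                    n_beats_used=9,
                    n_fused=0,
                )
            )
    return records, summaries, ga, values_before


class TestCohortTable:
    def test_hand_computed_values(self, ref):
        records, summaries, ga, values = _tiny_cohort(ref)
        table = ck.build_cohort_table(summaries, records, ref)
        am = table[(table.variable == "Am") & (table.timing == "before")]
        mean, sd = ref.mean("Am", "LV", ga), ref.sd("Am", "LV", ga)
        np.testing.assert_allclose(am["value"], values)
        np.testing.assert_allclose(am["z"], (np.array(values) - mean) / sd)
        hb_mom = 100.0 / ref.hb_median_at(ga)
        assert am["hb_mom"].iloc[0] == pytest.approx(hb_mom)
        assert set(am["anemia_grade"]) == {ck.classify_anemia(hb_mom)}

    def test_summary_tables_match_hand_arithmetic(self, ref):
        records, summaries, ga, values = _tiny_cohort(ref)
        table = ck.build_cohort_table(summaries, records, ref)
        tabs = build_tables(table)
        row = tabs["before_summary"]
        row = row[(row.wall == "LV") & (row.variable == "Am")].iloc[0]
        assert row.abs_mean == pytest.approx(np.mean(values))
        assert row.abs_sd == pytest.approx(np.std(values, ddof=1))
        mean, sd = ref.mean("Am", "LV", ga), ref.sd("Am", "LV", ga)
        assert row.z_mean == pytest.approx((np.mean(values) - mean) / sd)
        # paired difference: each fetus dropped exactly 1 cm/s
        ch = tabs["paired_changes"]
        ch = ch[(ch.wall == "LV") & (ch.variable == "Am")].iloc[0]
        assert ch.abs_median_delta == pytest.approx(-1.0)
        assert ch.z_median_delta == pytest.approx(-1.0 / sd)

    def test_row_order_invariance(self, ref):
        records, summaries, *_ = _tiny_cohort(ref)
        t1 = ck.build_cohort_table(summaries, records, ref)
        t2 = ck.build_cohort_table(list(reversed(summaries)), records, ref)
        a = build_tables(t1)["before_summary"]
        b = build_tables(t2)["before_summary"]
        pd.testing.assert_frame_equal(a, b)


class TestOutlierAudit:
    def _cohort(self, ref):
        records, summaries, *_ = _tiny_cohort(ref)
        return ck.build_cohort_table(summaries, records, ref)

    def test_injected_outlier_flagged(self, ref):
        table = self._cohort(ref)
        table.loc[table.index[0], "z"] = 9.0
        _, flags = outlier_audit(table, threshold=4.0)
        assert len(flags) == 1
        assert flags["z"].iloc[0] == 9.0

    def test_infinite_threshold_flags_nothing(self, ref):
        table = self._cohort(ref)
        table.loc[table.index[0], "z"] = 9.0
        audited, flags = outlier_audit(table, threshold=np.inf)
        assert flags.empty
        assert len(audited) == len(table)

    def test_drop_removes_flagged_rows(self, ref):
        table = self._cohort(ref)
        table.loc[table.index[0], "z"] = 9.0
        audited, flags = outlier_audit(table, threshold=4.0, drop=True)
        assert len(audited) == len(table) - 1


class TestNullBehavior:
    def test_null_cohort_mostly_non_significant(self, ref):
        """With all imposed effects zeroed the paired tests reject at the
        nominal rate only."""
        rejections = 0
        reps = 40
        for seed in range(reps):
            cfg = ck.CohortSimConfig(
                n_fetuses=20,
                walls=("LV",),
                post_iut_delta_z={},
                slope_em_z_per_mom=0.0,
                seed=seed,
            )
            sim = ck.simulate_cohort(cfg, ref, render_traces=False)
            t = sim.truth.pivot_table(index="fetus_id", columns="timing", values="z_Sm_LV")
            r = ck.paired_wilcoxon(t["before"], t["after"])
            rejections += r.p_value < 0.05
        assert rejections / reps <= 0.2
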