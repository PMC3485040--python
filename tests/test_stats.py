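import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import scanqa as sq


def brute_force_anova(groups):
    """Sums-of-squares oracle written out longhand."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - np.mean(g)) ** 2 for x in g) for g in groups)
    k, n = len(groups), len(allv)
    return (ssb / (k - 1)) / (ssw / (n - k))


def brute_force_icc31(x):
    """Two-way decomposition oracle for ICC(3,1), fully spelled out."""
    n, k = x.shape
    grand = x.mean()
    ss_sub = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ss_cond = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((x - grand) ** 2).sum()
    bms = ss_sub / (n - 1)
    ems = (ss_tot - ss_sub - ss_cond) / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        res = sq.one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.f == 0.0
        assert res.p == 1.0

    def test_df_3_conditions_6_subjects(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=6) for _ in range(3)]
        res = sq.one_way_anova(groups)
        assert (res.df_between, res.df_within) == (2, 15)

    def test_matches_brute_force_and_scipy(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(loc=m, size=n) for m, n in [(0, 4), (0.5, 6), (1.0, 5)]]
        res = sq.one_way_anova(groups)
        assert res.f == pytest.approx(brute_force_anova(groups), abs=1e-12)
        f_sp, p_sp = sps.f_oneway(*groups)
        assert res.f == pytest.approx(f_sp, rel=1e-12)
        assert res.p == pytest.approx(p_sp, rel=1e-9)

    def test_shift_scale_invariance(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=5) for _ in range(3)]
        f1 = sq.one_way_anova(groups).f
        f2 = sq.one_way_anova([7.7 * g + 3.1 for g in groups]).f
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sq.one_way_anova([[1.0], [2.0, 3.0]])


class TestAnovaFromSummary:
    def test_flat_means_give_f_zero(self):
        res = sq.anova_from_summary([0.44, 0.44, 0.44], [0.03, 0.04, 0.05], 6)
        assert round(res.f, 2) == 0.0
        assert (res.df_between, res.df_within) == (2, 15)
        assert res.p == pytest.approx(1.0)

    def test_reconstruction_matches_raw_anova(self):
        # synthesize balanced groups, summarize, reconstruct
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc=m, scale=1.0, size=8) for m in (0.0, 0.4, 0.9)]
        means = [g.mean() for g in groups]
        ses = [g.std(ddof=1) / np.sqrt(8) for g in groups]
        direct = sq.one_way_anova(groups)
        recon = sq.anova_from_summary(means, ses, 8)
        assert recon.f == pytest.approx(direct.f, rel=1e-9)
        assert (recon.df_between, recon.df_within) == (direct.df_between, direct.df_within)

    def test_two_groups_equal_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(loc=0.8, size=10)
        means = [a.mean(), b.mean()]
        ses = [a.std(ddof=1) / np.sqrt(10), b.std(ddof=1) / np.sqrt(10)]
        res = sq.anova_from_summary(means, ses, 10)
        t, _ = sps.ttest_ind(a, b)
        assert res.f == pytest.approx(t**2, rel=1e-12)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            sq.anova_from_summary([1, 2], [0.0, 0.1], 5)


class TestIcc:
    def test_perfect_reliability(self):
        table = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3]], float)
        res = sq.icc_consistency(table)
        assert res.icc == 1.0
        assert res.ems == pytest.approx(0.0)

    def test_all_equal_flagged_undefined(self):
        res = sq.icc_consistency(np.full((4, 3), 5.0))
        assert not res.defined
        assert np.isnan(res.icc)

    def test_matches_brute_force_3x3(self):
        rng = np.random.default_rng(5)
        table = rng.normal(size=(3, 3))
        res = sq.icc_consistency(table)
        assert res.icc_raw == pytest.approx(brute_force_icc31(table), abs=1e-12)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(6)
        subj_effect = rng.normal(scale=2.0, size=8)
        table = subj_effect[:, None] + rng.normal(scale=1.0, size=(8, 3))
        res = sq.icc_consistency(table)
        import pingouin as pg

        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "rater": np.tile(np.arange(3), 8),
                "score": table.ravel(),
            }
        )
        icc3 = pg.intraclass_corr(long, targets="subject", raters="rater",
                                  ratings="score")
        # ICC(C,1): single-rater consistency, the Shrout-Fleiss ICC(3,1)
        expected = float(icc3.loc[icc3["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert res.icc_raw == pytest.approx(expected, abs=1e-9)

    def test_null_noise_near_zero(self):
        raws = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            raws.append(sq.icc_consistency(rng.normal(size=(50, 3))).icc_raw)
        assert abs(np.mean(raws)) < 0.15

    def test_condition_shift_and_affine_invariance(self):
        rng = np.random.default_rng(7)
        table = rng.normal(size=(6, 3)) + rng.normal(scale=3, size=(6, 1))
        base = sq.icc_consistency(table).icc_raw
        shifted = table + np.array([10.0, -5.0, 2.0])  # per-condition constants
        assert sq.icc_consistency(shifted).icc_raw == pytest.approx(base, abs=1e-9)
        rescaled = 4.2 * table - 11.0
        assert sq.icc_consistency(rescaled).icc_raw == pytest.approx(base, abs=1e-9)

    def test_variance_component_recovery(self):
        # ICC(3,1) estimates sigma_b^2 / (sigma_b^2 + sigma_e^2)
        sigma_b, sigma_e = 2.0, 1.0
        target = sigma_b**2 / (sigma_b**2 + sigma_e**2)
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            table = (
                rng.normal(scale=sigma_b, size=(100, 1))
                + rng.normal(scale=sigma_e, size=(100, 3))
            )
            estimates.append(sq.icc_consistency(table).icc_raw)
        mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - target) < 3 * mc_se + 0.01

    def test_incomplete_table_rejected(self):
        table = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError):
            sq.icc_consistency(table)


class TestPairedT:
    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError):
            sq.paired_ttest([1, 2, 3], [1, 2, 3])

    def test_consistent_difference_is_significant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=6)
        b = a - (1.0 + 1e-6 * rng.normal(size=6))
        t, p = sq.paired_ttest(a, b)
        assert t > 100
        assert p < 1e-3

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=12), rng.normal(size=12)
        t, p = sq.paired_ttest(a, b)
        t_sp, p_sp = sps.ttest_rel(a, b)
        assert t == pytest.approx(t_sp, rel=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-9)


class TestMetricReport:
    @staticmethod
    def _table(values):
        rows = []
        n, k = values.shape
        for i in range(n):
            for j in range(k):
                rows.append((f"s{i}", str(j + 1), "m", values[i, j]))
        return sq.MetricTable(
            pd.DataFrame(rows, columns=["subject", "condition", "metric", "value"])
        )

    def test_df_and_icc_for_6x3(self):
        rng = np.random.default_rng(10)
        values = rng.normal(scale=0.1, size=(6, 3)) + rng.normal(scale=2, size=(6, 1))
        summaries = sq.metric_report(self._table(values), reference_condition="2")
        s = summaries[0]
        assert (s.anova.df_between, s.anova.df_within) == (2, 15)
        assert s.icc.icc > 0.9  # dominant subject variance
        assert set(s.posthoc) == {"1", "3"}

    def test_constant_per_subject_gives_icc_one(self):
        values = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
        summaries = sq.metric_report(self._table(values))
        assert summaries[0].icc.icc == 1.0

    def test_incomplete_table_skips_icc(self):
        frame = pd.DataFrame(
            [("a", "1", "m", 1.0), ("a", "2", "m", 2.0),
             ("b", "1", "m", 3.0), ("b", "2", "m", 2.5),
             ("c", "1", "m", 1.5)],
            columns=["subject", "condition", "metric", "value"],
        )
        summaries = sq.metric_report(sq.MetricTable(frame))
        assert summaries[0].icc is None
        assert any("ICC skipped" in w for w in summaries[0].warnings)

    def test_duplicate_cells_rejected(self):
        frame = pd.DataFrame(
            [("a", "1", "m", 1.0), ("a", "1", "m", 2.0)],
            columns=["subject", "condition", "metric", "value"],
        )
        with pytest.raises(ValueError):
            sq.MetricTable(frame)
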