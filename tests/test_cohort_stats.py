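import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from gliomicro.cohort_stats import (
    aggregate_roi,
    chi_square,
    compare_groups,
    delong_compare,
    exclusion_filter,
    metric_table,
    roc_analysis,
    table1,
    table2,
)
from gliomicro.phantom import CohortConfig, make_cohort
from gliomicro.protocol_io import ROISet


def _roiset(*masks, ref=None):
    return ROISet(tumor_rois=list(masks), reference_roi=ref)


class TestAggregateROI:
    def test_constant_map(self):
        m = np.full((4, 4, 1), 2.0)
        roi = np.zeros((4, 4, 1), bool)
        roi[1:3, 1:3, 0] = True
        assert aggregate_roi({"x": m}, _roiset(roi))["x"] == 2.0

    def test_equal_roi_weighting(self):
        vol = np.zeros((6, 6, 1))
        r1 = np.zeros_like(vol, bool)
        r2 = np.zeros_like(vol, bool)
        r1[0, :2, 0] = True          # 2 voxels, mean 1.0
        r2[3, :4, 0] = True          # 4 voxels, mean 3.0
        vol[0, :2, 0] = 1.0
        vol[3, :4, 0] = 3.0
        out = aggregate_roi({"x": vol}, _roiset(r1, r2))
        assert out["x"] == 2.0        # mean of ROI means, not pooled voxels
        pooled = vol[r1 | r2].mean()  # 2.333... — documents the difference
        assert abs(pooled - 7 / 3) < 1e-12

    def test_normalization_ratio(self):
        vol = np.zeros((4, 4, 1))
        roi = np.zeros_like(vol, bool)
        ref = np.zeros_like(vol, bool)
        roi[0, 0, 0] = True
        ref[3, 3, 0] = True
        vol[0, 0, 0] = 3.0
        vol[3, 3, 0] = 2.0
        out = aggregate_roi({"x": vol}, _roiset(roi, ref=ref), normalize=True)
        assert out["x_norm"] == 1.5

    def test_grid_mismatch(self):
        roi = np.ones((2, 2, 1), bool)
        with pytest.raises(ValueError):
            aggregate_roi({"x": np.zeros((3, 3, 1))}, _roiset(roi))


class TestCompareGroups:
    def test_identical_groups_maximal_p(self, rng):
        g = rng.normal(size=25)
        res = compare_groups(np.concatenate([g, g]),
                             np.array([0] * 25 + [1] * 25))
        assert res.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_huge_effect_tiny_p(self, rng):
        x = np.concatenate([rng.normal(0, 1, 25), rng.normal(5, 1, 23)])
        res = compare_groups(x, np.array([0] * 25 + [1] * 23))
        assert res.pvalue < 1e-6

    def test_heavy_tails_route_to_mannwhitney(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([sps.t(2).rvs(40, random_state=rng),
                            sps.t(2).rvs(40, random_state=rng)])
        res = compare_groups(x, np.array([0] * 40 + [1] * 40))
        assert res.test == "mann-whitney"

    def test_constant_feature_flagged(self):
        res = compare_groups(np.ones(10), np.array([0] * 5 + [1] * 5))
        assert res.pvalue == 1.0 and res.test == "constant"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.arange(5.0), np.array([0, 0, 1, 1, 1]))


class TestChiSquare:
    @pytest.mark.parametrize("table,printed,dp", [
        ([[19, 9], [6, 14]], 0.010, 3),    # lesion margin
        ([[11, 17], [14, 5]], 0.020, 3),   # pathological grading (N = 47)
        ([[7, 6], [18, 17]], 0.882, 3),    # midline invasion
        ([[11, 12], [14, 11]], 0.571, 3),  # lesion location
        ([[9, 13], [16, 10]], 0.154, 3),   # lesion size
    ])
    def test_reported_clinical_tables(self, table, printed, dp):
        assert round(chi_square(table).pvalue, dp) == printed

    def test_independence(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [3, 4]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[1, -2], [3, 4]])

    @given(st.lists(st.lists(st.integers(1, 20), min_size=2, max_size=4),
                    min_size=2, max_size=4).filter(
                        lambda t: len({len(r) for r in t}) == 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_brute_force_oracle(self, table):
        """Pearson statistic equals the explicit expected-count sum."""
        t = np.array(table, float)
        n = t.sum()
        exp = np.outer(t.sum(1), t.sum(0)) / n
        stat = ((t - exp) ** 2 / exp).sum()
        dof = (t.shape[0] - 1) * (t.shape[1] - 1)
        res = chi_square(table)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.pvalue == pytest.approx(sps.chi2.sf(stat, dof), rel=1e-12)


def _auc_brute(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1]))
        assert (r.auc, r.sensitivity, r.specificity) == (1.0, 1.0, 1.0)

    def test_all_ties(self):
        r = roc_analysis(np.ones(8), np.array([0, 1] * 4))
        assert r.auc == 0.5

    def test_pairwise_identity(self):
        r = roc_analysis(np.array([1, 2, 3, 4, 5, 6.0]), np.array([0, 1, 0, 1, 0, 1]))
        assert r.auc == pytest.approx(6 / 9)

    @given(st.lists(st.integers(0, 4), min_size=2, max_size=8).filter(
        lambda s: len(s) >= 2),
        st.data())
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_exhaustive_pair_oracle(self, scores, data):
        labels = data.draw(st.lists(st.integers(0, 1), min_size=len(scores),
                                    max_size=len(scores)))
        if len(set(labels)) < 2:
            return
        brute = _auc_brute(scores, labels)
        auc = roc_analysis(np.array(scores, float), np.array(labels)).auc
        assert auc == pytest.approx(max(brute, 1 - brute), abs=1e-12)

    def test_orientation_flip_flagged(self):
        r = roc_analysis(np.array([4, 3, 2, 1.0]), np.array([0, 0, 1, 1]))
        assert r.flipped and r.auc == 1.0

    def test_ci_contains_auc(self, rng):
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        y = np.array([0] * 30 + [1] * 30)
        r = roc_analysis(x, y)
        assert r.ci_low <= r.auc <= r.ci_high


class TestDeLong:
    def test_self_comparison(self, rng):
        x = rng.normal(size=40)
        y = np.array([0, 1] * 20)
        res = delong_compare(x, x, y)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_strong_vs_null_feature(self):
        rng = np.random.default_rng(9)
        y = np.array([0] * 100 + [1] * 100)
        strong = y * 1.8 + rng.normal(size=200)   # AUC ~ 0.9
        null = rng.normal(size=200)               # AUC ~ 0.5
        assert delong_compare(strong, null, y).pvalue < 0.01

    def test_row_permutation_invariance(self, rng):
        y = np.array([0, 1] * 15)
        a = rng.normal(size=30) + y
        b = rng.normal(size=30)
        z0 = delong_compare(a, b, y).statistic
        perm = rng.permutation(30)
        z1 = delong_compare(a[perm], b[perm], y[perm]).statistic
        assert z0 == pytest.approx(z1, abs=1e-12)


class TestExclusionFilter:
    def test_reported_patient_flow(self):
        """169 screened candidates minus the three stated exclusion
        groups leaves the 48 analysed patients."""
        n = 169
        flags = pd.DataFrame(False, index=range(n),
                             columns=["no_routine_mri", "incomplete_resection",
                                      "no_postop_mri"])
        flags.iloc[:42, 0] = True
        flags.iloc[42:45, 1] = True
        flags.iloc[45:121, 2] = True
        included, counts = exclusion_filter(flags)
        assert counts == {"no_routine_mri": 42, "incomplete_resection": 3,
                          "no_postop_mri": 76}
        assert included.sum() == 48

    def test_no_flags_identity(self):
        flags = pd.DataFrame(False, index=range(5), columns=["a"])
        inc, counts = exclusion_filter(flags)
        assert inc.all() and counts == {"a": 0}

    def test_all_flagged_empty(self):
        flags = pd.DataFrame(True, index=range(5), columns=["a"])
        inc, counts = exclusion_filter(flags)
        assert not inc.any() and counts == {"a": 5}


class TestCohortTables:
    def test_metric_table_and_bh(self):
        c = make_cohort(CohortConfig(seed=5))
        tab = metric_table(c.features, c.labels)
        assert len(tab) == 21
        assert ((tab["pvalue_bh"] >= tab["pvalue"] - 1e-12).all())
        # strong effect metric should be detected
        assert tab.loc["De_perp", "pvalue"] < 0.01

    def test_table2_marks_nonsignificant_na(self):
        c = make_cohort(CohortConfig(seed=5))
        t2 = table2(c.features, c.labels)
        sig = metric_table(c.features, c.labels)["pvalue"] < 0.05
        assert t2.loc[~sig, "auc"].isna().all()
        assert ((t2.loc[sig, "auc"] >= 0.5) & (t2.loc[sig, "auc"] <= 1)).all()

    def test_table1_runs_on_synthetic_clinical(self):
        c = make_cohort(CohortConfig(seed=5))
        t1 = table1(c.clinical)
        assert "age" in t1.index and "lesion_margin" in t1.index
        assert ((t1["pvalue"].dropna() >= 0) & (t1["pvalue"].dropna() <= 1)).all()
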