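"""ROI aggregation, univariate group statistics, chi-square tests and ROC
analysis for the two-group cohort.

Statistical conventions (documented, not configurable unless noted):

* Continuous features: Shapiro-Wilk normality check on each group at
  alpha = 0.05; if both normal, a two-sample t-test (pooled variance,
  with a Welch fallback when Levene rejects homogeneity), otherwise a
  Mann-Whitney U test with normal approximation and tie correction.
* Categorical tables: Pearson chi-square without continuity correction,
  df = (R-1)(C-1).
* ROC: AUC by the Mann-Whitney identity (ties half-credit), DeLong
  variance for confidence intervals and for paired AUC comparison;
  operating point at the maximal Youden index (ties broken toward the
  lowest threshold).
* No multiple-testing correction is applied to the per-metric p-values;
  a Benjamini-Hochberg column is emitted alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import METRICS
from .protocol_io import ClinicalTable, ROISet

__all__ = [
    "TestResult", "ROCResult",
    "aggregate_roi", "compare_groups", "chi_square",
    "roc_analysis", "delong_compare", "exclusion_filter",
    "metric_table", "table1", "table2",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.pvalue <= 1 or np.isnan(self.pvalue)):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    threshold: float
    flipped: bool = False
    auc_variance: float = 0.0


def aggregate_roi(maps: dict, rois: ROISet, normalize: bool = False) -> dict:
    """Per-metric patient value: mean over tumor-ROI means (ROIs equally
    weighted); with ``normalize`` the contralateral-WM-normalised value is
    added under ``<metric>_norm``."""
    out = {}
    for name, vol in maps.items():
        roi_means = []
        for roi in rois.tumor_rois:
            if vol.shape != roi.shape:
                raise ValueError(f"map {name!r} and ROI grids differ")
            roi_means.append(float(vol[roi].mean()))
        value = float(np.mean(roi_means))
        out[name] = value
        if normalize:
            if rois.reference_roi is None:
                raise ValueError("normalization requested without a reference ROI")
            ref = float(vol[rois.reference_roi].mean())
            out[f"{name}_norm"] = value / ref
    return out


def compare_groups(feature: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> TestResult:
    """Normality-routed two-group comparison (see module docstring)."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    g0, g1 = x[y == 0], x[y == 1]
    if len(g0) < 3 or len(g1) < 3:
        raise ValueError("each group needs n >= 3")
    detail = {
        "mean_0": float(g0.mean()), "sd_0": float(g0.std(ddof=1)),
        "mean_1": float(g1.mean()), "sd_1": float(g1.std(ddof=1)),
        "median_0": float(np.median(g0)), "median_1": float(np.median(g1)),
    }
    if np.ptp(x) == 0:
        return TestResult("constant", 0.0, 1.0, {**detail, "flag": "constant feature"})

    def _normal(g):
        if np.ptp(g) == 0:
            return False
        return stats.shapiro(g).pvalue > alpha

    if _normal(g0) and _normal(g1):
        homo = stats.levene(g0, g1).pvalue > alpha
        res = stats.ttest_ind(g0, g1, equal_var=homo)
        name = "t-test" if homo else "welch-t"
        return TestResult(name, float(res.statistic), float(res.pvalue), detail)
    res = stats.mannwhitneyu(g0, g1, alternative="two-sided", method="asymptotic")
    return TestResult("mann-whitney", float(res.statistic), float(res.pvalue), detail)


def chi_square(table) -> TestResult:
    """Pearson chi-square on an R x C count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2-D array of non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(t, correction=False)
    return TestResult("chi-square", float(chi2), float(p),
                      {"dof": int(dof), "expected": expected})


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """Per-sample DeLong placement values and the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    allv = np.concatenate([pos, neg])
    t_all = _midrank(allv)
    t_pos = _midrank(pos)
    t_neg = _midrank(neg)
    v_pos = (t_all[:m] - t_pos) / n           # P(score_neg < score_pos) per positive
    v_neg = 1.0 - (t_all[m:] - t_neg) / m     # per negative
    auc = float(v_pos.mean())
    return auc, v_pos, v_neg


def _auc_covariance(v_pos: np.ndarray, v_neg: np.ndarray) -> float:
    m, n = len(v_pos), len(v_neg)
    s10 = np.var(v_pos, ddof=1) if m > 1 else 0.0
    s01 = np.var(v_neg, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_analysis(feature: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Single-feature ROC with DeLong CI and the Youden operating point.

    Orientation is auto-flipped (and flagged) so the reported AUC is
    >= 0.5.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels).astype(int)
    auc, vp, vn = _delong_placements(x, y)
    flipped = auc < 0.5
    if flipped:
        x = -x
        auc, vp, vn = _delong_placements(x, y)
    var = _auc_covariance(vp, vn)
    half = 1.96 * np.sqrt(var)
    # operating point: predict positive when score >= threshold
    thresholds = np.unique(x)
    best = None
    for thr in thresholds:  # ascending; ties keep the lowest threshold
        pred = x >= thr
        sens = float(np.mean(pred[y == 1]))
        spec = float(np.mean(~pred[y == 0]))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    _, thr, sens, spec = best
    thr_out = -thr if flipped else thr
    return ROCResult(auc=auc, ci_low=max(0.0, auc - half), ci_high=min(1.0, auc + half),
                     sensitivity=sens, specificity=spec, threshold=float(thr_out),
                     flipped=flipped, auc_variance=float(var))


def delong_compare(feature_a: np.ndarray, feature_b: np.ndarray,
                   labels: np.ndarray) -> TestResult:
    """Paired DeLong Z test for the difference of two correlated AUCs."""
    y = np.asarray(labels).astype(int)
    a_auc, a_vp, a_vn = _delong_placements(np.asarray(feature_a, float), y)
    b_auc, b_vp, b_vn = _delong_placements(np.asarray(feature_b, float), y)
    m, n = len(a_vp), len(a_vn)
    s10 = np.cov(np.vstack([a_vp, b_vp]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([a_vn, b_vn]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = float(S[0, 0] + S[1, 1] - 2 * S[0, 1])
    diff = a_auc - b_auc
    if var <= 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return TestResult("delong-z", float(z), p,
                      {"auc_a": a_auc, "auc_b": b_auc, "diff": diff})


def exclusion_filter(flags: pd.DataFrame, criteria: list | None = None):
    """Apply exclusion criteria in order; True flags a candidate for removal.

    Returns (included boolean Series, removal counts per criterion in
    application order, counting only candidates not already removed).
    """
    criteria = list(criteria) if criteria is not None else list(flags.columns)
    surviving = pd.Series(True, index=flags.index)
    counts = {}
    for c in criteria:
        removed = surviving & flags[c].astype(bool)
        counts[c] = int(removed.sum())
        surviving &= ~removed
    return surviving, counts


# ---------------------------------------------------------------------------
# Cohort-level tables
# ---------------------------------------------------------------------------

def metric_table(features: pd.DataFrame, labels: np.ndarray,
                 metrics: list | None = None) -> pd.DataFrame:
    """Per-metric group comparison with a Benjamini-Hochberg column."""
    metrics = metrics or [m for m in METRICS if m in features.columns]
    rows = []
    for m in metrics:
        r = compare_groups(features[m].to_numpy(), labels)
        rows.append({"metric": m, "test": r.test, "statistic": r.statistic,
                     "pvalue": r.pvalue,
                     "mean_nonrec": r.detail["mean_0"], "sd_nonrec": r.detail["sd_0"],
                     "mean_rec": r.detail["mean_1"], "sd_rec": r.detail["sd_1"]})
    out = pd.DataFrame(rows).set_index("metric")
    p = out["pvalue"].to_numpy()
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    bh = np.empty_like(p)
    bh[order] = np.clip(ranked, 0, 1)
    out["pvalue_bh"] = bh
    return out


def table2(features: pd.DataFrame, labels: np.ndarray,
           metrics: list | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-metric ROC summary (AUC, 95% CI, sensitivity, specificity).

    Following the study's convention, metrics whose group comparison is
    not significant at ``alpha`` are marked not-applicable (NaN row).
    """
    metrics = metrics or [m for m in METRICS if m in features.columns]
    stats_tab = metric_table(features, labels, metrics)
    rows = []
    for m in metrics:
        if stats_tab.loc[m, "pvalue"] < alpha:
            r = roc_analysis(features[m].to_numpy(), labels)
            rows.append({"metric": m, "auc": r.auc, "ci_low": r.ci_low,
                         "ci_high": r.ci_high, "sensitivity": r.sensitivity,
                         "specificity": r.specificity, "flipped": r.flipped})
        else:
            rows.append({"metric": m, "auc": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "sensitivity": np.nan, "specificity": np.nan, "flipped": False})
    return pd.DataFrame(rows).set_index("metric")


_T1_CATEGORICAL = ["gender", "midline_invasion", "lesion_location", "lesion_size",
                   "lesion_margin", "histological_class", "who_grade", "therapy"]


def table1(clinical: ClinicalTable) -> pd.DataFrame:
    """Clinical-characteristics summary with per-row tests.

    Age uses the routed continuous comparison; categorical rows use
    Pearson chi-square on the group-by-category count table.  Unknown
    WHO grades are dropped from the grading test.
    """
    df = clinical.df
    y = clinical.labels
    rows = [{"characteristic": "age", "test": "continuous",
             "pvalue": compare_groups(df["age"].to_numpy(), y).pvalue}]
    for col in _T1_CATEGORICAL:
        if col not in df.columns:
            continue
        sub = df
        if col == "who_grade":
            sub = df[df[col].astype(str) != "unknown"]
        counts = pd.crosstab(sub[col], sub["group"])
        try:
            p = chi_square(counts.to_numpy()).pvalue
        except ValueError:
            p = np.nan
        rows.append({"characteristic": col, "test": "chi-square", "pvalue": p})
    return pd.DataFrame(rows).set_index("characteristic")
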