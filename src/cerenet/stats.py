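"""Group comparison machinery: normality-gated test selection, covariate
control, Bonferroni-corrected region-wise comparisons.

Policy (recorded in every result):

* Shapiro–Wilk normality per group at alpha 0.05; both groups must pass
  for the parametric branch.
* Parametric branch — two-tailed independent t-test on values linearly
  residualized against the covariates (age, sex), with a t-based 95% CI
  of the mean difference.
* Nonparametric branch — Mann–Whitney U on raw values, with the
  Hodges–Lehmann shift estimate and its distribution-free 95% CI.
* Categorical variables — Pearson chi-square.
* Region-wise comparisons use Bonferroni correction with m equal to the
  compartment's ROI count (0.05/26 cerebellar, 0.05/72 cortical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NormalityResult", "GroupComparison", "normality_check",
    "compare_groups", "chi_square_categorical", "log_transform_nonnormal",
    "bonferroni", "roi_wise_comparison", "roi_wise_bc_comparison",
]

NORMALITY_ALPHA = 0.05


@dataclass
class NormalityResult:
    passed: bool
    p_value: float
    note: str = ""


@dataclass
class GroupComparison:
    """One feature's two-group comparison (baseline-table row layout)."""

    feature_name: str
    groups: tuple[str, str]
    test_used: str                    # 't' | 'mann-whitney' | 'chi-square'
    statistic: float
    p_value: float
    difference: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    corrected_alpha: float = 0.05
    significant: bool = False
    detail: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "feature": self.feature_name,
            "group_a": self.groups[0], "group_b": self.groups[1],
            "test": self.test_used, "statistic": self.statistic,
            "difference": self.difference,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value,
            "corrected_alpha": self.corrected_alpha,
            "significant": self.significant,
        }


def normality_check(values: np.ndarray,
                    alpha: float = NORMALITY_ALPHA) -> NormalityResult:
    """Shapiro–Wilk test; pass when p >= alpha.

    A constant vector cannot be normal in the test's sense and fails with
    a note; n < 3 raises.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(values) == 0:
        return NormalityResult(False, 0.0, note="constant vector")
    stat, p = sps.shapiro(values)
    return NormalityResult(bool(p >= alpha), float(p))


def residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of values on [1, covariates] by least squares."""
    values = np.asarray(values, dtype=float)
    x = np.column_stack([np.ones(len(values)),
                         np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    resid = values - x @ beta
    return resid + values.mean()      # keep the overall location


def _hodges_lehmann_ci(a: np.ndarray, b: np.ndarray,
                       confidence: float = 0.95) -> tuple[float, float, float]:
    """Hodges–Lehmann shift estimate (median of pairwise b - a differences)
    with the distribution-free CI from the Mann-Whitney U distribution
    (normal approximation for the rank cutoffs)."""
    diffs = np.sort((b[:, None] - a[None, :]).ravel())
    est = float(np.median(diffs))
    n1, n2 = len(a), len(b)
    n12 = n1 * n2
    z = sps.norm.ppf(0.5 + confidence / 2)
    k = int(np.floor(n12 / 2 - z * np.sqrt(n12 * (n1 + n2 + 1) / 12.0)))
    k = max(k, 0)
    lo = float(diffs[k]) if k < n12 else float(diffs[0])
    hi = float(diffs[n12 - k - 1]) if n12 - k - 1 >= 0 else float(diffs[-1])
    return est, lo, hi


def compare_groups(values_a: np.ndarray, values_b: np.ndarray,
                   covariates_a: np.ndarray | None = None,
                   covariates_b: np.ndarray | None = None,
                   feature_name: str = "",
                   groups: tuple[str, str] = ("A", "B"),
                   corrected_alpha: float = 0.05,
                   force_test: str | None = None) -> GroupComparison:
    """Two-group comparison with normality-gated test selection.

    If both groups pass Shapiro–Wilk the t branch runs (on covariate-
    residualized values when covariates are given); otherwise Mann–Whitney
    on raw values.  ``force_test`` overrides the gate ('t' or
    'mann-whitney').  The reported difference is b - a.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need n >= 3")
    if force_test is None:
        na, nb = normality_check(a), normality_check(b)
        use_t = na.passed and nb.passed
        detail = {"shapiro_p_a": na.p_value, "shapiro_p_b": nb.p_value}
    else:
        use_t = force_test == "t"
        detail = {"forced": force_test}

    if use_t:
        if covariates_a is not None and covariates_b is not None:
            pooled = np.concatenate([a, b])
            cov = np.vstack([np.atleast_2d(np.asarray(covariates_a, float)),
                             np.atleast_2d(np.asarray(covariates_b, float))])
            if cov.shape[0] != len(pooled):
                cov = cov.T
            resid = residualize(pooled, cov)
            a_use, b_use = resid[: len(a)], resid[len(a):]
            detail["covariate_adjusted"] = True
        else:
            a_use, b_use = a, b
            detail["covariate_adjusted"] = False
        stat, p = sps.ttest_ind(b_use, a_use, equal_var=True)
        diff = float(b_use.mean() - a_use.mean())
        se = np.sqrt(a_use.var(ddof=1) / len(a) + b_use.var(ddof=1) / len(b))
        dof = len(a) + len(b) - 2
        tcrit = sps.t.ppf(0.975, dof)
        lo, hi = diff - tcrit * se, diff + tcrit * se
        test = "t"
    else:
        stat, p = sps.mannwhitneyu(b, a, alternative="two-sided")
        diff, lo, hi = _hodges_lehmann_ci(a, b)
        test = "mann-whitney"
    return GroupComparison(feature_name=feature_name, groups=groups,
                           test_used=test, statistic=float(stat),
                           p_value=float(p), difference=float(diff),
                           ci_low=float(lo), ci_high=float(hi),
                           corrected_alpha=corrected_alpha,
                           significant=bool(p < corrected_alpha),
                           detail=detail)


def chi_square_categorical(table: np.ndarray,
                           feature_name: str = "",
                           groups: tuple[str, str] = ("A", "B"),
                           corrected_alpha: float = 0.05) -> GroupComparison:
    """Pearson chi-square on a contingency table of counts (no Yates
    correction, matching the textbook statistic)."""
    table = np.asarray(table)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)):
            raise ValueError("counts must be integers")
        table = np.round(table).astype(int)
    res = sps.chi2_contingency(table, correction=False)
    if (res.expected_freq < 1).any():
        import warnings
        warnings.warn("chi-square expected cell count < 1", RuntimeWarning)
    return GroupComparison(feature_name=feature_name, groups=groups,
                           test_used="chi-square",
                           statistic=float(res.statistic),
                           p_value=float(res.pvalue),
                           corrected_alpha=corrected_alpha,
                           significant=bool(res.pvalue < corrected_alpha))


def log_transform_nonnormal(features: pd.DataFrame,
                            normality: dict[str, NormalityResult] | None = None,
                            epsilon: float = 1e-6,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Natural-log transform of the features that fail normality.

    Nonpositive features are shifted by (epsilon - min) before the log;
    every action is recorded in the returned ledger frame.
    """
    out = features.copy()
    records = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        res = (normality or {}).get(col) or normality_check(vals)
        shift = 0.0
        if not res.passed:
            mn = vals.min()
            if mn <= 0:
                shift = epsilon - mn
            out[col] = np.log(vals + shift)
        records.append({"feature": col, "shapiro_p": res.p_value,
                        "transformed": not res.passed,
                        "base": "natural" if not res.passed else "",
                        "shift": shift, "note": res.note})
    return out, pd.DataFrame(records)


def bonferroni(p_values: np.ndarray, m: int,
               family_alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Significance mask p < family_alpha / m and the corrected alpha."""
    if m < 1:
        raise ValueError("m must be >= 1")
    corrected = family_alpha / m
    return np.asarray(p_values, dtype=float) < corrected, corrected


def roi_wise_comparison(feature_table: pd.DataFrame, labels: pd.Series,
                        group_a: str, group_b: str,
                        covariates: pd.DataFrame | None = None,
                        m: int | None = None,
                        family_alpha: float = 0.05,
                        ) -> tuple[list[GroupComparison], pd.DataFrame]:
    """Bonferroni-corrected per-ROI comparison of a subjects x ROI table.

    m defaults to the ROI (column) count.  Returns the comparisons plus a
    tidy frame with per-ROI direction ('increase' means higher in
    group_b).
    """
    labels = labels.reindex(feature_table.index)
    ids_a = labels.index[labels == group_a]
    ids_b = labels.index[labels == group_b]
    if len(ids_a) < 3 or len(ids_b) < 3:
        raise ValueError(f"groups {group_a!r}/{group_b!r} need >= 3 "
                         "subjects each")
    m = m or feature_table.shape[1]
    _, corrected = bonferroni([1.0], m, family_alpha)
    cov_a = cov_b = None
    if covariates is not None:
        cov = covariates.copy()
        if "sex" in cov.columns and cov["sex"].dtype == object:
            cov["sex"] = (cov["sex"] == "M").astype(float)
        cov_a = cov.loc[ids_a].to_numpy(dtype=float)
        cov_b = cov.loc[ids_b].to_numpy(dtype=float)
    results = []
    rows = []
    for roi in feature_table.columns:
        res = compare_groups(feature_table.loc[ids_a, roi].to_numpy(),
                             feature_table.loc[ids_b, roi].to_numpy(),
                             covariates_a=cov_a, covariates_b=cov_b,
                             feature_name=str(roi),
                             groups=(group_a, group_b),
                             corrected_alpha=corrected)
        results.append(res)
        rows.append({**res.as_row(),
                     "direction": ("increase" if res.difference > 0
                                   else "decrease")})
    return results, pd.DataFrame(rows)


def roi_wise_bc_comparison(nodal_auc: pd.DataFrame, labels: pd.Series,
                           group_a: str, group_b: str,
                           metric: str = "betweenness",
                           covariates: pd.DataFrame | None = None,
                           family_alpha: float = 0.05,
                           ) -> tuple[list[GroupComparison], pd.DataFrame]:
    """Region-wise comparison of a nodal AUC metric (betweenness by
    default) between two groups, Bonferroni m = ROI count.

    ``nodal_auc`` is the subjects x 'metric.roi' frame produced by
    ``cohort_metric_tables``.
    """
    prefix = f"{metric}."
    cols = [c for c in nodal_auc.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"no columns for nodal metric {metric!r}")
    table = nodal_auc[cols].rename(columns=lambda c: c[len(prefix):])
    return roi_wise_comparison(table, labels, group_a, group_b,
                               covariates=covariates, m=len(cols),
                               family_alpha=family_alpha)
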