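"""Cohort statistics: normality-gated group comparisons, Pearson
correlations with Benjamini-Hochberg FDR, partial correlation, and ICC
reproducibility from a two-way ANOVA decomposition."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_used: str  # "student_t" or "mann_whitney"
    statistic: float
    p: float
    summary_a: str
    summary_b: str
    normality_p: tuple[float, float]


@dataclass(frozen=True)
class CorrelationEntry:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int
    q: float = np.nan
    covariate: str | None = None


def _mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.3g} ± {x.std(ddof=1):.3g}"


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.3g} ({q1:.3g}, {q3:.3g})"


def compare_groups(a, b, normality_alpha: float = 0.05,
                   welch: bool = False, variable: str = "") -> GroupComparison:
    """Two-group comparison with normality-gated test selection.

    Shapiro-Wilk is run per group; if both p-values are at or above
    ``normality_alpha`` a two-sided two-sample t-test is used (pooled
    variance by default, Welch with ``welch=True``) and the groups are
    summarized as mean +/- SD, otherwise a two-sided Mann-Whitney U test
    with median (IQR) summaries.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")

    p_norm_a = sst.shapiro(a).pvalue
    p_norm_b = sst.shapiro(b).pvalue
    if p_norm_a >= normality_alpha and p_norm_b >= normality_alpha:
        res = sst.ttest_ind(a, b, equal_var=not welch)
        return GroupComparison(variable, "student_t", float(res.statistic),
                               float(res.pvalue), _mean_sd(a), _mean_sd(b),
                               (float(p_norm_a), float(p_norm_b)))
    res = sst.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(variable, "mann_whitney", float(res.statistic),
                           float(res.pvalue), _median_iqr(a), _median_iqr(b),
                           (float(p_norm_a), float(p_norm_b)))


def correlation_matrix(table: pd.DataFrame,
                       pairs: list[tuple[str, str]]) -> list[CorrelationEntry]:
    """Pearson correlations for a declared family of variable pairs.

    Two-sided p per pair, then Benjamini-Hochberg step-up q across the
    family (the family is exactly the supplied pair list, never inferred).
    Complete cases only per pair; a constant variable raises.
    """
    if not pairs:
        raise ValueError("empty pair family")
    raw: list[CorrelationEntry] = []
    for x_name, y_name in pairs:
        sub = table[[x_name, y_name]].dropna()
        if len(sub) < 4:
            raise ValueError(f"pair ({x_name}, {y_name}) has fewer than 4 complete cases")
        x = sub[x_name].to_numpy(float)
        y = sub[y_name].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"constant variable in pair ({x_name}, {y_name})")
        r, p = sst.pearsonr(x, y)
        raw.append(CorrelationEntry(x_name, y_name, float(r), float(p), len(sub)))

    q = multipletests([e.p for e in raw], method="fdr_bh")[1]
    return [
        CorrelationEntry(e.var_x, e.var_y, e.r, e.p, e.n, q=float(qi))
        for e, qi in zip(raw, q)
    ]


def partial_correlation(x, y, covariate, var_x: str = "x", var_y: str = "y",
                        covariate_name: str = "covariate") -> CorrelationEntry:
    """Pearson correlation of x and y after residualizing on one covariate.

    Both variables are regressed (with intercept) on the covariate; the
    correlation of the residuals is tested against a t reference with
    n - 3 degrees of freedom.  A constant covariate falls back to the
    plain correlation with a warning.
    """
    data = np.column_stack([
        np.asarray(x, dtype=float),
        np.asarray(y, dtype=float),
        np.asarray(covariate, dtype=float),
    ])
    data = data[np.all(np.isfinite(data), axis=1)]
    n = data.shape[0]
    if n < 5:
        raise ValueError("partial correlation needs at least 5 complete cases")
    xv, yv, cv = data.T

    if cv.std() == 0:
        warnings.warn("constant covariate; falling back to plain correlation")
        r, p = sst.pearsonr(xv, yv)
        return CorrelationEntry(var_x, var_y, float(r), float(p), n)

    design = np.column_stack([np.ones(n), cv])
    res_x = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    res_y = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    # a variable collinear with the covariate leaves numerically-zero
    # residuals; its partial correlation is 0 by convention
    if (res_x.std() <= 1e-10 * max(xv.std(), 1e-30)
            or res_y.std() <= 1e-10 * max(yv.std(), 1e-30)):
        return CorrelationEntry(var_x, var_y, 0.0, 1.0, n,
                                covariate=covariate_name)
    r = float(np.corrcoef(res_x, res_y)[0, 1])
    df = n - 3
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sst.t.sf(abs(t), df)
    return CorrelationEntry(var_x, var_y, r, float(p), n, covariate=covariate_name)


def icc_reproducibility(ratings) -> dict[str, float]:
    """Intra-rater reproducibility from two repeated measurements.

    ``ratings`` is an (n_subjects, 2) array.  Both the two-way consistency
    coefficient ``ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)`` and the
    two-way absolute-agreement single-measure coefficient (which also
    penalizes systematic shifts between measurements via the column mean
    square) are returned, since reports often conflate the two.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("ratings must be an (n_subjects, 2) array")
    if not np.all(np.isfinite(x)):
        raise ValueError("every subject needs both measurements")
    n, k = x.shape
    if n < 5:
        raise ValueError("ICC needs at least 5 subjects")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    icc_consistency = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    icc_agreement = (ms_r - ms_e) / (
        ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    )
    return {
        "icc_consistency": float(icc_consistency),
        "icc_agreement": float(icc_agreement),
    }
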