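"""Summaries and group statistics for Z-deviation maps.

Per-subject deviation indices are mean-based: overall = mean Z over
regions, positive = mean of max(Z, 0), negative = mean of min(Z, 0), so
overall = positive + negative holds exactly.  Extreme deviations use a
strict |Z| > threshold rule (default 2.6, two-sided p < 0.005).

Comparison statistics mirror standard practice: Welch t-tests with
pooled-SD Cohen's d, one-way ANOVA and ANCOVA with partial eta squared,
Cramer's V for contingency tables, Pearson correlations, and
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

EXTREME_Z = 2.6


@dataclass
class ComparisonResult:
    statistic: float
    p: float
    effect_size: float
    effect_kind: str  # "cohens_d" | "cramers_v" | "partial_eta2"
    group_ns: tuple[int, ...]
    q: float | None = None  # BH-adjusted, filled in by the caller


def deviation_indices(z: pd.DataFrame, threshold: float = EXTREME_Z) -> pd.DataFrame:
    """Per-subject indices and extreme-region counts from a Z map."""
    arr = z.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("Z map contains non-finite values")
    pos = np.clip(arr, 0, None)
    neg = np.clip(arr, None, 0)
    out = pd.DataFrame(
        {
            "overall_index": arr.mean(axis=1),
            "positive_index": pos.mean(axis=1),
            "negative_index": neg.mean(axis=1),
            "extreme_positive": (arr > threshold).sum(axis=1),
            "extreme_negative": (arr < -threshold).sum(axis=1),
        },
        index=z.index,
    )
    out["extreme_total"] = out["extreme_positive"] + out["extreme_negative"]
    return out


def overlap_map(z: pd.DataFrame, threshold: float = EXTREME_Z) -> pd.DataFrame:
    """Per-region percentage of subjects with extreme +/- deviations."""
    if len(z) < 1:
        raise ValueError("need at least one subject")
    arr = z.to_numpy(dtype=float)
    n = arr.shape[0]
    return pd.DataFrame(
        {
            "percent_positive": 100.0 * (arr > threshold).sum(axis=0) / n,
            "percent_negative": 100.0 * (arr < -threshold).sum(axis=0) / n,
        },
        index=z.columns,
    )


def prevalence_stats(z: pd.DataFrame, threshold: float = EXTREME_Z) -> dict:
    """Cohort-level prevalence of extreme deviations.

    Percentages of subjects with at least one extreme region (any /
    positive / negative) and of regions with at least one extreme subject.
    """
    arr = z.to_numpy(dtype=float)
    pos = arr > threshold
    neg = arr < -threshold
    n, r = arr.shape
    return {
        "subjects_any_extreme_pct": 100.0 * (pos | neg).any(axis=1).mean(),
        "subjects_positive_extreme_pct": 100.0 * pos.any(axis=1).mean(),
        "subjects_negative_extreme_pct": 100.0 * neg.any(axis=1).mean(),
        "regions_any_extreme_pct": 100.0 * (pos | neg).any(axis=0).mean(),
        "regions_positive_extreme_pct": 100.0 * pos.any(axis=0).mean(),
        "regions_negative_extreme_pct": 100.0 * neg.any(axis=0).mean(),
        "n_subjects": n,
        "n_regions": r,
    }


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's d (n-1 denominators per group)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def compare_groups_t(a, b, equal_var: bool = False) -> ComparisonResult:
    """Two-sample t-test (Welch by default) with pooled-SD Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        statistic=float(t),
        p=float(p),
        effect_size=cohens_d(a, b),
        effect_kind="cohens_d",
        group_ns=(len(a), len(b)),
    )


def anova_partial_eta(groups) -> ComparisonResult:
    """One-way ANOVA with partial eta^2 = SS_effect / (SS_effect + SS_error)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    ns = [len(g) for g in groups]
    if sum(ns) <= len(groups):
        raise ValueError("too few observations")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_effect = sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups))
    ss_error = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_effect + ss_error <= 0:
        raise ValueError("degenerate (zero total variance)")
    f, p = stats.f_oneway(*groups)
    return ComparisonResult(
        statistic=float(f),
        p=float(p),
        effect_size=float(ss_effect / (ss_effect + ss_error)),
        effect_kind="partial_eta2",
        group_ns=tuple(ns),
    )


def ancova_interaction(
    outcome, factor, covariate
) -> dict[str, ComparisonResult]:
    """ANCOVA outcome ~ factor * covariate with type-III tests.

    Returns partial eta^2 and p for the factor main effect, the covariate
    main effect, and the factor x covariate interaction.  Sum-to-zero
    factor coding makes the type-III decomposition well defined.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(outcome, dtype=float),
            "g": pd.Categorical([str(v) for v in factor]),
            "x": np.asarray(covariate, dtype=float),
        }
    )
    model = smf.ols("y ~ C(g, Sum) * x", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("collinear design")
    table = sm.stats.anova_lm(model, typ=3)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    out = {}
    names = {"C(g, Sum)": "factor", "x": "covariate", "C(g, Sum):x": "interaction"}
    for row, label in names.items():
        ss = float(table.loc[row, "sum_sq"])
        out[label] = ComparisonResult(
            statistic=float(table.loc[row, "F"]),
            p=float(table.loc[row, "PR(>F)"]),
            effect_size=ss / (ss + ss_resid),
            effect_kind="partial_eta2",
            group_ns=(len(df),),
        )
    return out


def cramers_v(table) -> ComparisonResult:
    """Cramer's V = sqrt(chi2 / (n * (min(r, c) - 1))) for a contingency table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if table.sum() <= 0:
        raise ValueError("empty table")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    n = table.sum()
    v = np.sqrt(chi2 / (n * (min(table.shape) - 1)))
    return ComparisonResult(
        statistic=float(chi2),
        p=float(p),
        effect_size=float(v),
        effect_kind="cramers_v",
        group_ns=tuple(int(x) for x in table.sum(axis=1)),
    )


def pearson_r(x, y) -> ComparisonResult:
    """Product-moment correlation with the t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return ComparisonResult(
        statistic=float(r),
        p=float(p),
        effect_size=float(r),
        effect_kind="pearson_r",
        group_ns=(len(x),),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def regionwise_group_test(
    z_a: pd.DataFrame, z_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-region Welch t-tests of two Z maps with BH-FDR, tidy output."""
    rows = []
    for col in z_a.columns:
        res = compare_groups_t(z_a[col], z_b[col])
        rows.append(
            {"region": col, "t": res.statistic, "p": res.p, "cohens_d": res.effect_size}
        )
    out = pd.DataFrame(rows).set_index("region")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
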