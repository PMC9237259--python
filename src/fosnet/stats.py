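"""Group-difference and correlation statistics.

One-way fixed-effects ANOVA with Tukey HSD post hoc tests is the per-region
group comparison; Pearson correlation matrices relate regional activity to
behavior and tyrosine-hydroxylase measures. ANOVA can also be reconstructed
exactly from published mean/SEM/n summaries, which makes printed F statistics
recomputable without raw data: with equal group sizes the summary-based
decomposition is algebraically identical to the raw-data one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AnovaResult, CohortMatrix, ValidationError

__all__ = [
    "PairwiseComparison",
    "CorrelationReport",
    "oneway_anova",
    "anova_from_summary",
    "tukey_hsd",
    "pearson_matrix",
    "anova_table_by_region",
]


@dataclass(frozen=True)
class PairwiseComparison:
    """One Tukey-adjusted pairwise group contrast."""

    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float


@dataclass
class CorrelationReport:
    """Symmetric Pearson r/p matrices with significance flags.

    ``star`` marks pairs with p below ``alpha`` (default 0.001, the
    convention used for correlation heatmaps here). Undefined correlations
    (zero-variance columns, too few complete pairs) are NaN, never 0.
    """

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    star: pd.DataFrame
    alpha: float = 0.001
    n_obs: pd.DataFrame | None = None

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                rows.append({
                    "var_a": a, "var_b": b,
                    "r": self.r.at[a, b], "p": self.p.at[a, b],
                    "star": bool(self.star.at[a, b]),
                })
        return pd.DataFrame(rows)


def _check_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(values_by_group) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    out = {}
    for g, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 values")
        out[g] = arr
    return out


def oneway_anova(values_by_group: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA from raw per-group values."""
    groups = _check_groups(values_by_group)
    arrays = list(groups.values())
    df_between = len(arrays) - 1
    df_within = sum(a.size for a in arrays) - len(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0:
        grand = np.concatenate(arrays).mean()
        ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df_between=df_between,
                               df_within=df_within, p=1.0)
        return AnovaResult(F=float("inf"), df_between=df_between,
                           df_within=df_within, p=0.0)
    f, p = sps.f_oneway(*arrays)
    return AnovaResult(F=float(f), df_between=df_between,
                       df_within=df_within, p=float(p))


def anova_from_summary(
    means: Mapping[str, float],
    sems: Mapping[str, float],
    n: Mapping[str, int],
) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group mean, SEM, and n.

    SS_between comes from the n-weighted group means around the grand mean;
    MS_within pools per-group variances recovered as ``sem^2 * n``. For
    summaries computed from raw data this reproduces the raw-data F exactly.
    Zero pooled variance with unequal means yields ``F = inf, p = 0``.
    """
    if set(means) != set(sems) or set(means) != set(n):
        raise ValidationError("means, sems, and n must cover the same groups")
    groups = list(means)
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    for g in groups:
        if n[g] < 2:
            raise ValidationError(f"group {g!r} has n < 2")
        if sems[g] < 0:
            raise ValidationError(f"group {g!r} has negative SEM")

    ns = np.array([n[g] for g in groups], dtype=float)
    mu = np.array([means[g] for g in groups], dtype=float)
    var = np.array([sems[g] ** 2 * n[g] for g in groups], dtype=float)

    df_between = len(groups) - 1
    df_within = int(ns.sum()) - len(groups)
    grand = float((ns * mu).sum() / ns.sum())
    ss_between = float((ns * (mu - grand) ** 2).sum())
    ms_between = ss_between / df_between
    ms_within = float(((ns - 1) * var).sum() / (ns - 1).sum())

    if ms_within == 0.0:
        if ms_between == 0.0:
            return AnovaResult(F=0.0, df_between=df_between,
                               df_within=df_within, p=1.0)
        return AnovaResult(F=float("inf"), df_between=df_between,
                           df_within=df_within, p=0.0)
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(F=float(f), df_between=df_between,
                       df_within=df_within, p=p)


def tukey_hsd(
    values_by_group: Mapping[str, Sequence[float]],
) -> list[PairwiseComparison]:
    """Tukey honestly-significant-difference test over all group pairs.

    Adjusted p-values come from the studentized-range distribution with the
    pooled within-group variance; all unordered pairs are returned in the
    input's group order.
    """
    groups = _check_groups(values_by_group)
    labels = list(groups)
    res = sps.tukey_hsd(*[groups[g] for g in labels])
    out = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        out.append(PairwiseComparison(
            group_a=labels[i],
            group_b=labels[j],
            mean_diff=float(groups[labels[i]].mean() - groups[labels[j]].mean()),
            p_adj=float(min(1.0, res.pvalue[i, j])),
        ))
    return out


def pearson_matrix(
    cohort: CohortMatrix | pd.DataFrame,
    columns: Sequence[str],
    alpha: float = 0.001,
    min_obs: int = 3,
) -> CorrelationReport:
    """Pairwise Pearson correlations with per-pair listwise deletion.

    Each pair uses its own complete observations, so missing values in one
    optional column do not shrink n for unrelated pairs. Pairs with fewer
    than ``min_obs`` complete observations or a zero-variance member are NaN.
    """
    df = cohort.data if isinstance(cohort, CohortMatrix) else cohort
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"columns absent from cohort: {missing}")
    cols = list(columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    nobs = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i, j in itertools.combinations(range(k), 2):
        pair = df[[cols[i], cols[j]]].dropna()
        nobs[i, j] = nobs[j, i] = len(pair)
        if len(pair) < min_obs:
            continue
        x = pair[cols[i]].to_numpy(dtype=float)
        y = pair[cols[j]].to_numpy(dtype=float)
        if x.std() == 0.0 or y.std() == 0.0:
            continue  # correlation undefined; stays NaN
        rij, pij = sps.pearsonr(x, y)
        r[i, j] = r[j, i] = float(rij)
        p[i, j] = p[j, i] = float(pij)
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    star = (p_df < alpha) & np.isfinite(p_df)
    np.fill_diagonal(star.values, False)
    return CorrelationReport(variables=cols, r=r_df, p=p_df, star=star,
                             alpha=alpha,
                             n_obs=pd.DataFrame(nobs, index=cols, columns=cols))


def anova_table_by_region(cohort: CohortMatrix) -> pd.DataFrame:
    """Per-region one-way ANOVA across the cohort's groups (no correction).

    Returns a DataFrame indexed by region with F, df, and p columns. No
    multiple-testing correction is applied by default, matching the
    per-region reporting convention of small c-Fos mapping studies; apply
    e.g. Benjamini-Hochberg downstream if desired.
    """
    rows = {}
    for region in cohort.regions:
        by_group = {
            g: cohort.data.loc[cohort.data["group"] == g, region].to_numpy()
            for g in cohort.groups
            if (cohort.data["group"] == g).sum() >= 2
        }
        res = oneway_anova(by_group)
        rows[region] = {
            "F": res.F, "df_between": res.df_between,
            "df_within": res.df_within, "p": res.p,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "region"
    return out
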