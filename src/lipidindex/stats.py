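"""Group comparison of functional indices.

The per-index comparison uses Welch's unequal-variance t test for
significance and reports the log2 fold change of group means with a
first-order error-propagation (delta-method) standard error:

    log2FC = log2(m_exp / m_ctrl)
    SE     = (1/ln 2) * sqrt( s_exp^2/(n_exp m_exp^2) + s_ctrl^2/(n_ctrl m_ctrl^2) )

which is coherent with the Welch test (both work from within-group means,
variances and sample sizes).  Effect-size metrics for biomarker ranking are
the rank-statistic ROC AUC (polarity-corrected to >= 0.5), pooled-SD
Cohen's d and the post-hoc power of the two-sample t test at the observed
|d| computed from the noncentral-t distribution.  P-values are unadjusted
by default (a small fixed panel of <= 42 indices is tested); an optional
Benjamini-Hochberg adjustment can be requested.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import IndexMatrix


def welch_compare(x, y) -> tuple[float, float, float]:
    """Welch's t statistic, Welch-Satterthwaite df and two-sided p.

    Degenerate zero-variance groups are resolved by the separation limit:
    p = 1 when the means coincide, p = 0 when they do not.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_compare needs at least 2 values per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return math.inf if x.mean() > y.mean() else -math.inf, float(len(x) + len(y) - 2), 0.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def log2fc_with_se(x, y) -> tuple[float, float]:
    """log2 fold change of group means and its delta-method SE."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    if mx <= 0 or my <= 0:
        raise ValueError("log2 fold change requires positive group means")
    vx = x.var(ddof=1) / (len(x) * mx**2)
    vy = y.var(ddof=1) / (len(y) * my**2)
    return math.log2(mx / my), math.sqrt(vx + vy) / math.log(2)


def cohens_d(x, y) -> float:
    """Classic pooled-SD Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    diff = x.mean() - y.mean()
    if sp2 == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / math.sqrt(sp2)


def rank_auc(x, y) -> float:
    """ROC AUC from the Mann-Whitney rank statistic, polarity-corrected.

    The returned value is max(AUC, 1-AUC), so an index that separates the
    groups in either direction scores the same.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
    auc = u / (len(x) * len(y))
    return max(auc, 1.0 - auc)


def ttest_power(effect_size: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Post-hoc power of the two-sample t test at effect size |d|.

    Exact noncentral-t computation: with df = n1+n2-2 and noncentrality
    nc = |d| sqrt(n1 n2/(n1+n2)), power = P(|T'| > t_crit).
    """
    d = abs(effect_size)
    if not math.isfinite(d):
        return 1.0
    df = n1 + n2 - 2
    nc = d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    power = float(1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    if not math.isfinite(power):  # nct loses precision at extreme nc
        power = float(sps.norm.sf(tcrit - nc) + sps.norm.cdf(-tcrit - nc))
    return power


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-tolerant)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def welch_anova(groups: Sequence[np.ndarray]) -> tuple[float, float, float, float]:
    """One-way Welch ANOVA (unequal variances): F, df1, df2, p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("welch_anova needs >=2 groups with >=2 values each")
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    if np.any(v == 0):
        v = np.where(v == 0, np.finfo(float).tiny, v)
    w = n / v
    mw = (w * m).sum() / w.sum()
    a = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    b = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = a / b
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * lam)
    return float(f), df1, float(df2), float(sps.f.sf(f, df1, df2))


def _group_values(values: pd.Series, groups: pd.Series, label) -> np.ndarray:
    v = values[groups.index[groups == label]]
    return v.dropna().to_numpy(dtype=float)


def compare_all_indices(
    index_matrix: IndexMatrix,
    groups: pd.Series,
    group_exp: str,
    group_ctrl: str,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-index two-group comparison table.

    One row per index evaluated in at least one sample; rows lacking two
    non-NA values per group or a positive mean in either group are flagged
    not-comparable and carry NaN statistics.  ``significant`` requires
    p < p_threshold AND |log2FC| >= fc_threshold.
    """
    defs = {d.index_id: d for d in index_matrix.library}
    rows = []
    values = index_matrix.values
    for index_id in values.columns:
        col = values[index_id]
        if col.notna().sum() == 0:
            continue
        d = defs[index_id]
        x = _group_values(col, groups, group_exp)
        y = _group_values(col, groups, group_ctrl)
        row = {
            "index_id": index_id,
            "name": d.display_name,
            "category": d.category,
            "n_exp": len(x),
            "n_ctrl": len(y),
            "mean_exp": x.mean() if len(x) else np.nan,
            "mean_ctrl": y.mean() if len(y) else np.nan,
            "log2fc": np.nan,
            "se_log2fc": np.nan,
            "t": np.nan,
            "df": np.nan,
            "p_value": np.nan,
            "cohens_d": np.nan,
            "auc": np.nan,
            "power": np.nan,
            "comparable": False,
            "significant": False,
            "interpretation": "",
        }
        if len(x) >= 2 and len(y) >= 2 and x.mean() > 0 and y.mean() > 0:
            t, df_, p = welch_compare(x, y)
            lfc, se = log2fc_with_se(x, y)
            row.update(
                log2fc=lfc,
                se_log2fc=se,
                t=t,
                df=df_,
                p_value=p,
                cohens_d=cohens_d(x, y),
                auc=rank_auc(x, y),
                power=ttest_power(cohens_d(x, y), len(x), len(y), alpha),
                comparable=True,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    if fdr:
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
        pcol = "p_adjusted"
    else:
        pcol = "p_value"
    sig = (table[pcol] < p_threshold) & (table["log2fc"].abs() >= fc_threshold)
    table["significant"] = sig.fillna(False)
    table.loc[table["significant"], "interpretation"] = [
        defs[i].phrase_high if f > 0 else defs[i].phrase_low
        for i, f in zip(
            table.loc[table["significant"], "index_id"],
            table.loc[table["significant"], "log2fc"],
        )
    ]
    return table


def anova_all_indices(
    index_matrix: IndexMatrix,
    groups: pd.Series,
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-index one-way Welch ANOVA across >2 groups (no fold change)."""
    if labels is None:
        labels = list(pd.unique(groups))
    defs = {d.index_id: d for d in index_matrix.library}
    rows = []
    for index_id in index_matrix.values.columns:
        col = index_matrix.values[index_id]
        if col.notna().sum() == 0:
            continue
        gs = [_group_values(col, groups, lab) for lab in labels]
        d = defs[index_id]
        row = {
            "index_id": index_id,
            "name": d.display_name,
            "category": d.category,
            "F": np.nan,
            "df1": np.nan,
            "df2": np.nan,
            "p_value": np.nan,
            "comparable": False,
        }
        if all(len(g) >= 2 for g in gs):
            try:
                f, df1, df2, p = welch_anova(gs)
                row.update(F=f, df1=df1, df2=df2, p_value=p, comparable=True)
            except ValueError:
                pass
        for lab, g in zip(labels, gs):
            row[f"mean_{lab}"] = g.mean() if len(g) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def functional_dominance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-category dominance: sum of significant |log2FC| over the number
    of indices effectively evaluated (comparable) in that category."""
    rows = []
    for cat in ("Structural", "Signaling", "Energy"):
        sub = table[table["category"] == cat] if not table.empty else table
        n_eval = int(sub["comparable"].sum()) if not table.empty else 0
        if n_eval == 0:
            rows.append(
                {"category": cat, "dominance": np.nan, "n_evaluated": 0, "n_significant": 0}
            )
            continue
        sig = sub[sub["significant"]]
        rows.append(
            {
                "category": cat,
                "dominance": float(sig["log2fc"].abs().sum()) / n_eval,
                "n_evaluated": n_eval,
                "n_significant": int(len(sig)),
            }
        )
    return pd.DataFrame(rows)


def biomarker_rank(
    index_matrix: IndexMatrix,
    groups: pd.Series,
    group_exp: str,
    group_ctrl: str,
    alpha: float = 0.05,
    top: int = 20,
) -> pd.DataFrame:
    """Rank indices by discriminative performance.

    Ordering: ascending Welch p, then descending polarity-corrected AUC,
    then descending |Cohen's d|; the output is truncated to the top ``top``
    rows.  Constant (zero-variance, equal-mean) indices score AUC 0.5 and
    d = 0 and therefore rank last.
    """
    table = compare_all_indices(
        index_matrix, groups, group_exp, group_ctrl, alpha=alpha
    )
    table = table[table["comparable"]].copy()
    if table.empty:
        return table
    table["abs_d"] = table["cohens_d"].abs()
    table = table.sort_values(
        ["p_value", "auc", "abs_d"], ascending=[True, False, False], kind="mergesort"
    ).drop(columns=["abs_d", "significant", "interpretation"])
    table.insert(0, "rank", range(1, len(table) + 1))
    return table.head(top).reset_index(drop=True)


def correlation_matrix(
    index_matrix: IndexMatrix, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise-complete Pearson or Spearman correlations between indices.

    Indices never evaluated are dropped; zero-variance indices yield NaN
    correlations.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unsupported correlation method {method!r}")
    values = index_matrix.values
    values = values.loc[:, values.notna().sum(axis=0) > 0]
    if values.shape[0] < 3:
        raise ValueError("correlation matrix needs at least 3 samples")
    return values.corr(method=method, min_periods=3)
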