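"""Group-difference statistics: ANOVA with Tukey/LSD post-hoc, Kruskal-Wallis with
FDR, two-group fold-change tables with optional empirical-Bayes variance moderation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupTestResult:
    feature: str
    group_means: dict
    statistic: float  # F (ANOVA) or H (Kruskal-Wallis)
    p: float
    posthoc: pd.DataFrame  # pairwise comparisons
    q: Optional[float] = None


def anova_posthoc(values_by_group: dict, method: str = "tukey", feature: str = "") -> GroupTestResult:
    """Classical one-way ANOVA with Tukey HSD or Fisher LSD pairwise post-hoc tests.

    Tukey p-values use the studentized range distribution on the MSE; LSD uses
    unadjusted pooled-variance t tests.
    """
    if method not in ("tukey", "lsd"):
        raise ValueError(f"unknown post-hoc method {method!r}")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    names = list(groups)
    ns = np.array([len(groups[g]) for g in names])
    means = np.array([groups[g].mean() for g in names])
    N, k = int(ns.sum()), len(names)
    grand = np.concatenate([groups[g] for g in names]).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((groups[g] - groups[g].mean()) ** 2).sum() for g in names))
    df_b, df_w = k - 1, N - k
    mse = ss_within / df_w
    if mse == 0:
        F = 0.0 if ss_between == 0 else np.inf
    else:
        F = (ss_between / df_b) / mse
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    if F == 0:
        p = 1.0

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se_t = np.sqrt(mse * (1 / ns[i] + 1 / ns[j]))
            if method == "tukey":
                # studentized range statistic on the harmonic-style SE
                se_q = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
                qstat = abs(diff) / se_q if se_q > 0 else np.inf
                pp = float(stats.studentized_range.sf(qstat, k, df_w))
            else:
                tstat = abs(diff) / se_t if se_t > 0 else np.inf
                pp = float(2 * stats.t.sf(tstat, df_w))
            rows.append(
                {"group_a": names[i], "group_b": names[j], "diff": diff, "p": min(pp, 1.0)}
            )
    return GroupTestResult(
        feature=feature,
        group_means=dict(zip(names, means)),
        statistic=float(F),
        p=p,
        posthoc=pd.DataFrame(rows),
    )


def kruskal_wallis_h(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p; all-tied data gives H=0, p=1."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrs)
    return float(h), float(p)


def kruskal_fdr(
    log_table: pd.DataFrame, groups: pd.Series, fdr_threshold: float = 0.7
) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis across diagnosis groups with BH FDR across features.

    ``fdr_threshold`` is a display/selection threshold (features flagged below
    it), not a significance claim.
    """
    groups = groups.loc[log_table.index]
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    masks = {g: (groups == g).to_numpy() for g in levels}
    for feat in log_table.columns:
        v = log_table[feat].to_numpy(dtype=float)
        h, p = kruskal_wallis_h([v[m] for m in masks.values()])
        rows.append({"feature": feat, "H": h, "p": p})
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["flagged"] = out["q"] < fdr_threshold
    return out.sort_values("p")


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse chi-square prior (d0, s0^2) to observed variances.

    Uses the log-variance moments: E log s^2 = log s0^2 + digamma(df/2) -
    log(df/2) - digamma(d0/2) + log(d0/2) and Var log s^2 = trigamma(df/2) +
    trigamma(d0/2). Returns (inf, median s2) when the empirical spread is no
    wider than sampling noise (complete shrinkage).
    """
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        return np.inf, float(np.median(s2))
    e, v = z.mean(), z.var(ddof=1)
    excess = v - special.polygamma(1, df / 2)
    if excess <= 1e-8:
        s0 = np.exp(e - special.polygamma(0, df / 2) + np.log(df / 2))
        return np.inf, float(s0)

    def fn(d0):
        return special.polygamma(1, d0 / 2) - excess

    lo, hi = 1e-6, 1e6
    if fn(lo) < 0:  # excess larger than any achievable trigamma: tiny d0
        d0 = lo
    else:
        d0 = brentq(fn, lo, hi)
    s0 = np.exp(
        e
        - special.polygamma(0, df / 2)
        + np.log(df / 2)
        + special.polygamma(0, d0 / 2)
        - np.log(d0 / 2)
    )
    return float(d0), float(s0)


def moderated_ttest(
    xa: np.ndarray, xb: np.ndarray, prior_df: float, prior_var: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature moderated t: variances shrunk toward (prior_df, prior_var).

    With prior_df = 0 this reduces to the ordinary pooled two-sample t test.
    Returns (t, p) arrays over features (columns).
    """
    na, nb = xa.shape[0], xb.shape[0]
    df = na + nb - 2
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / df
    if prior_df == 0:
        s2_tilde, df_tot = s2, df
    elif np.isinf(prior_df):
        s2_tilde, df_tot = np.full_like(s2, prior_var), np.inf
    else:
        s2_tilde = (prior_df * prior_var + df * s2) / (prior_df + df)
        df_tot = df + prior_df
    diff = xa.mean(axis=0) - xb.mean(axis=0)
    se = np.sqrt(s2_tilde * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    if np.isinf(df_tot):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_tot)
    return t, p


def fold_change_table(
    log_table: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    moderation: str = "none",
) -> pd.DataFrame:
    """Per-feature log2 fold change (A minus B on the log2 scale) with t-test p.

    ``moderation='empirical_bayes'`` shrinks per-feature variances toward a
    prior fitted across features (moderated t); ``'none'`` is the ordinary
    two-sided pooled t test, which returns a missing p for zero-variance
    features.
    """
    if moderation not in ("none", "empirical_bayes"):
        raise ValueError(f"unknown moderation {moderation!r}")
    groups = groups.loc[log_table.index]
    xa = log_table.loc[(groups == group_a).to_numpy()].to_numpy(dtype=float)
    xb = log_table.loc[(groups == group_b).to_numpy()].to_numpy(dtype=float)
    if xa.shape[0] == 0 or xb.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    log2fc = xa.mean(axis=0) - xb.mean(axis=0)
    na, nb = xa.shape[0], xb.shape[0]
    df = na + nb - 2
    if moderation == "empirical_bayes":
        va = xa.var(axis=0, ddof=1)
        vb = xb.var(axis=0, ddof=1)
        s2 = ((na - 1) * va + (nb - 1) * vb) / df
        d0, s0 = _fit_variance_prior(s2, df)
        t, p = moderated_ttest(xa, xb, d0, s0)
    else:
        t, p = moderated_ttest(xa, xb, 0.0, 0.0)
        zero_var = (xa.var(axis=0) == 0) & (xb.var(axis=0) == 0)
        p = np.where(zero_var & (log2fc == 0), np.nan, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_log10 = -np.log10(p)
    out = pd.DataFrame(
        {
            "log2FC": log2fc,
            "t": t,
            "p": p,
            "neg_log10_p": neg_log10,
        },
        index=log_table.columns,
    )
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    return out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p-rank)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
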