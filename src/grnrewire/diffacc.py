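"""Moderated differential accessibility between ATAC sample groups.

Per-peak read densities are log2-transformed (with a +1 offset) and the two
groups compared with an empirical-Bayes moderated t-statistic: per-peak
residual variances s^2 with d residual degrees of freedom are shrunk towards
a common prior (d0, s0^2) fitted by method of moments to a scaled-F
distribution on the log variances, giving posterior variances

    s_post^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and moderated t with d0 + d degrees of freedom.  With d0 = 0 this is the
ordinary two-sample t; as d0 -> inf it approaches a pooled-variance z-like
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class VariancePrior:
    df_prior: float  # d0; may be inf
    var_prior: float  # s0^2


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df_residual: float) -> VariancePrior:
    """Method-of-moments fit of a scaled F prior to observed variances.

    Works on z = log(s^2), whose mean and excess variance over the known
    chi-square component identify (d0, s0^2).  When the observed spread does
    not exceed the chi-square component, d0 = inf (fully pooled variance).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        warnings.warn("too few positive variances; using pooled variance (d0=inf)")
        pooled = float(np.mean(s2[ok])) if ok.any() else 0.0
        return VariancePrior(np.inf, pooled)
    z = np.log(s2[ok])
    d = df_residual
    e = z - special.digamma(d / 2) + np.log(d / 2)
    ebar = float(np.mean(e))
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2))
    if excess <= 0:
        warnings.warn("no excess variance heterogeneity; using pooled prior (d0=inf)")
        return VariancePrior(np.inf, float(np.exp(ebar)))
    d0 = 2 * _trigamma_inverse(excess)
    s0 = float(np.exp(ebar + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return VariancePrior(d0, s0)


def moderated_differential_accessibility(
    density: pd.DataFrame,
    groups: pd.Series | dict | list,
    fc_threshold: float = 2.0,
    padj_threshold: float = 0.01,
    log_offset: float = 1.0,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential accessibility between two sample groups.

    Parameters
    ----------
    density
        peaks x samples read-density matrix (nonnegative).
    groups
        Group label per sample (two distinct labels).  logFC is reported as
        second group minus first group (labels in order of first appearance).
    fc_threshold, padj_threshold
        Peaks with |logFC| > log2(fc_threshold) and BH-adjusted p below
        ``padj_threshold`` are flagged significant.
    prior_df
        Override the fitted prior degrees of freedom d0 (0 recovers the
        ordinary t-test; ``None`` fits d0 from the data).

    Returns
    -------
    DataFrame indexed like ``density`` with columns ``logFC``, ``t``,
    ``pvalue``, ``padj``, ``direction`` and ``significant``.
    """
    groups = pd.Series(list(groups), index=density.columns)
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    g0 = density.columns[groups == labels[0]]
    g1 = density.columns[groups == labels[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("need >= 2 samples per group")

    x0 = np.log2(density[g0].to_numpy(dtype=float) + log_offset)
    x1 = np.log2(density[g1].to_numpy(dtype=float) + log_offset)
    n0, n1 = x0.shape[1], x1.shape[1]
    d = n0 + n1 - 2
    m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
    logfc = m1 - m0
    rss = ((x0 - m0[:, None]) ** 2).sum(axis=1) + ((x1 - m1[:, None]) ** 2).sum(axis=1)
    s2 = rss / d

    if prior_df is None:
        prior = fit_variance_prior(s2, d)
    else:
        prior = VariancePrior(
            float(prior_df),
            float(np.mean(s2)) if np.isinf(prior_df) else float(np.median(s2)),
        )
        if np.isfinite(prior.df_prior) and prior.df_prior > 0:
            prior = VariancePrior(prior.df_prior, fit_variance_prior(s2, d).var_prior)

    d0, s0 = prior.df_prior, prior.var_prior
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    padj = multipletests(p, method="fdr_bh")[1]
    sig = (np.abs(logfc) > np.log2(fc_threshold)) & (padj < padj_threshold)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "pvalue": p,
            "padj": padj,
            "direction": np.where(logfc >= 0, "up", "down"),
            "significant": sig,
        },
        index=density.index,
    )


def top_by_foldchange(
    table: pd.DataFrame, peaks: pd.DataFrame, n: int = 4000, direction: str = "up"
) -> pd.DataFrame:
    """Top-n peaks by signed logFC in one direction, ties broken by coordinate.

    ``table`` is a differential-accessibility table aligned row-for-row with
    ``peaks`` (chrom/start/end).  ``direction`` 'up' ranks by decreasing
    logFC, 'down' by increasing.
    """
    if n > len(table):
        raise ValueError(f"n={n} exceeds table size {len(table)}")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    merged = peaks[["chrom", "start", "end"]].copy()
    merged["logFC"] = table["logFC"].to_numpy()
    key = -merged["logFC"] if direction == "up" else merged["logFC"]
    order = np.lexsort((merged["start"].to_numpy(), merged["chrom"].to_numpy(), key.to_numpy()))
    return merged.iloc[order[:n]].reset_index(drop=True)
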