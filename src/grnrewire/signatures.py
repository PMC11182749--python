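"""Differential expression, signature definition and per-cell rank scoring.

State contrasts use the two-sided Wilcoxon rank-sum test per gene with
Bonferroni correction; logFC is the difference of mean log-normalised
expression.  Gene-set activity per cell is the Mann-Whitney-U-derived rank
score: with all genes ranked by decreasing expression in a cell and
signature-gene ranks capped at r_max + 1,

    U' = sum(capped ranks) - n(n+1)/2,   score = 1 - U' / (n * r_max)

clamped to [0, 1].  The score depends only on within-cell ranks, so it is
invariant under any monotone transform of a cell's expression values.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .grn import GRNResults


@dataclass
class SignatureDefinition:
    name: str
    genes: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        self.genes = tuple(sorted(set(self.genes)))


def wilcoxon_de(
    adata: ad.AnnData,
    group_a: str,
    group_b: str,
    layer: str = "lognorm",
    state_key: str = "state",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between two cell states.

    logFC is mean(layer in A) - mean(layer in B).  P-values use the
    tie-corrected normal approximation (exact enumeration for small
    tie-free groups) and are Bonferroni-adjusted over all tested genes.
    """
    labels = adata.obs[state_key].astype(str)
    ia = (labels == group_a).to_numpy()
    ib = (labels == group_b).to_numpy()
    if ia.sum() < 3 or ib.sum() < 3:
        raise ValueError("both groups need >= 3 cells")
    x = np.asarray(adata.layers[layer])
    xa, xb = x[ia], x[ib]
    logfc = xa.mean(axis=0) - xb.mean(axis=0)
    stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided", axis=0, method="auto")
    # constant genes give identical samples; define p = 1 there
    const = (xa.std(axis=0) == 0) & (xb.std(axis=0) == 0) & (
        np.abs(logfc) < 1e-12
    )
    p = np.where(const, 1.0, p)
    padj = np.minimum(p * x.shape[1], 1.0)
    return pd.DataFrame(
        {"logFC": logfc, "statistic": stat, "pvalue": p, "padj": padj},
        index=adata.var_names,
    )


def define_signature_from_de(
    de: pd.DataFrame,
    name: str = "signature",
    logfc_min: float = 0.5,
    padj_max: float = 0.05,
    direction: str = "up",
) -> SignatureDefinition:
    """Genes passing the logFC and adjusted-p thresholds in one direction."""
    if direction == "up":
        passing = de[(de["logFC"] > logfc_min) & (de["padj"] < padj_max)]
    elif direction == "down":
        passing = de[(de["logFC"] < -logfc_min) & (de["padj"] < padj_max)]
    else:
        raise ValueError("direction must be 'up' or 'down'")
    if len(passing) == 0:
        raise ValueError(
            f"no genes pass logFC {direction} > {logfc_min} and padj < {padj_max}; "
            "review thresholds"
        )
    return SignatureDefinition(
        name=name,
        genes=tuple(passing.index),
        provenance=f"DE {direction}, logFC>{logfc_min}, padj<{padj_max}",
    )


def regulator_signature(
    score_table: pd.DataFrame,
    grn: GRNResults,
    polarity: str = "positive",
    top_n: int = 10,
    connectivity_min: float = 0.1,
    name: str | None = None,
) -> SignatureDefinition:
    """Regulator signature: top-scoring TFs plus their strong GRN targets.

    Positive-regulator signatures take the ``top_n`` TFs by highest positive
    OE score or most negative KO score; negative-regulator signatures take
    the highest negative OE score or most positive KO score.  Their targets
    in ``grn`` with |connectivity| > ``connectivity_min`` complete the set.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    oe = score_table[score_table["mode"] == "OE"].set_index("tf")
    ko = score_table[score_table["mode"] == "KO"].set_index("tf")
    if polarity == "positive":
        ranking = pd.concat(
            [oe["sum_positive"], -ko["sum_negative"]], axis=1
        ).max(axis=1)
    else:
        ranking = pd.concat(
            [-oe["sum_negative"], ko["sum_positive"]], axis=1
        ).max(axis=1)
    top_tfs = (
        ranking.sort_index(kind="mergesort")
        .sort_values(ascending=False, kind="mergesort")
        .head(top_n)
        .index.tolist()
    )
    strong = grn.edges[
        grn.edges["regulator"].isin(top_tfs)
        & (grn.edges["coefficient"].abs() > connectivity_min)
    ]
    genes = set(top_tfs) | set(strong["target"])
    return SignatureDefinition(
        name=name or f"{polarity}_regulators",
        genes=tuple(genes),
        provenance=(
            f"top {top_n} {polarity}-PS TFs + targets with "
            f"|connectivity| > {connectivity_min}"
        ),
    )


def rank_signature_score(
    adata: ad.AnnData,
    signature: SignatureDefinition,
    r_max: int = 1500,
    layer: str = "lognorm",
) -> pd.Series:
    """Per-cell Mann-Whitney rank score of a gene signature in [0, 1]."""
    x = np.asarray(adata.layers[layer])
    if r_max >= x.shape[1]:
        raise ValueError(f"r_max={r_max} must be below the gene count {x.shape[1]}")
    present = [g for g in signature.genes if g in set(adata.var_names)]
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} is in the dataset")
    cols = [adata.var_names.get_loc(g) for g in present]
    # rank by decreasing expression with average ties, per cell
    ranks = stats.rankdata(-x, axis=1, method="average")
    sig_ranks = np.minimum(ranks[:, cols], r_max + 1)
    n = len(cols)
    u = sig_ranks.sum(axis=1) - n * (n + 1) / 2.0
    score = np.clip(1.0 - u / (n * r_max), 0.0, 1.0)
    return pd.Series(score, index=adata.obs_names, name=signature.name)
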