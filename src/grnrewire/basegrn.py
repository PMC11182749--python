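"""Candidate TF -> target network ("base GRN") from open chromatin.

A TF is a candidate regulator of a gene when a peak assigned to that gene
(nearest transcription start site within a maximum distance) carries a motif
hit for the TF.  The base GRN is a binary incidence structure with full
provenance: every (TF, gene) pair records the supporting peak, motif,
position, strand and score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    max_distance: int = 100_000,
) -> pd.Series:
    """Assign each peak to the gene with the nearest TSS.

    Distance is measured from the peak centre; peaks farther than
    ``max_distance`` from every TSS stay unassigned (NaN).  Equidistant ties
    resolve to the lexicographically smaller gene name.

    Returns a Series of gene names indexed by peak ``name`` (or positional
    index when no name column is present).
    """
    if len(tss) == 0:
        raise ValueError("TSS table must be nonempty")
    index = peaks["name"] if "name" in peaks.columns else peaks.index
    assigned = pd.Series(pd.NA, index=pd.Index(index, name="peak"), dtype=object)
    centres = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    for chrom in peaks["chrom"].unique():
        sel = (peaks["chrom"] == chrom).to_numpy()
        sub = tss[tss["chrom"] == chrom].sort_values(["tss", "gene"], kind="mergesort")
        if len(sub) == 0:
            continue
        positions = sub["tss"].to_numpy()
        genes = sub["gene"].to_numpy()
        for row, centre in zip(np.flatnonzero(sel), centres[sel]):
            dist = np.abs(positions - centre)
            best = dist.min()
            if best > max_distance:
                continue
            candidates = genes[dist == best]
            assigned.iloc[row] = min(candidates)
    return assigned


@dataclass
class BaseGRN:
    """Binary candidate-regulator incidence with per-pair provenance."""

    pairs: pd.DataFrame  # columns: tf, target
    provenance: pd.DataFrame  # columns: tf, target, peak, motif_id, position, strand, score
    genes: tuple[str, ...]

    @property
    def tfs(self) -> tuple[str, ...]:
        return tuple(sorted(self.pairs["tf"].unique()))

    def regulators_of(self, gene: str) -> tuple[str, ...]:
        return tuple(sorted(self.pairs.loc[self.pairs["target"] == gene, "tf"]))

    def as_pair_set(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.pairs[["tf", "target"]].itertuples(index=False)))

    def candidate_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {g: [] for g in self.genes}
        for tf, target in self.pairs[["tf", "target"]].itertuples(index=False):
            out.setdefault(target, []).append(tf)
        return {g: sorted(set(v)) for g, v in out.items()}


def build_base_grn(
    peak_to_gene: pd.Series,
    motif_hits: pd.DataFrame,
    tf_motif_map: pd.DataFrame,
    genes: list[str] | None = None,
) -> BaseGRN:
    """Assemble the base GRN from peak assignments and motif hits.

    Parameters
    ----------
    peak_to_gene
        Series mapping peak name -> gene (NaN entries ignored).
    motif_hits
        Hit table from :func:`grnrewire.motifs.scan_motifs` whose
        ``sequence`` column holds peak names.
    tf_motif_map
        DataFrame with ``tf`` and ``motif_id`` columns; a motif may serve
        several TFs and vice versa.
    genes
        Optional full gene universe (genes with no candidate regulator are
        retained in the GRN's gene list).
    """
    missing = set(motif_hits["motif_id"]) - set(tf_motif_map["motif_id"])
    if missing:
        raise ValueError(f"motif ids without TF mapping: {sorted(missing)}")
    hits = motif_hits.rename(columns={"sequence": "peak"})
    hits = hits.merge(tf_motif_map, on="motif_id", how="inner")
    assigned = peak_to_gene.dropna().rename("target")
    prov = hits.merge(assigned, left_on="peak", right_index=True, how="inner")
    prov = prov[["tf", "target", "peak", "motif_id", "position", "strand", "score"]]
    prov = prov.sort_values(
        ["tf", "target", "peak", "motif_id", "position"], kind="mergesort"
    ).reset_index(drop=True)
    pairs = (
        prov[["tf", "target"]]
        .drop_duplicates()
        .sort_values(["tf", "target"], kind="mergesort")
        .reset_index(drop=True)
    )
    universe = set(assigned.unique()) | set(pairs["target"])
    if genes is not None:
        universe |= set(genes)
    return BaseGRN(pairs=pairs, provenance=prov, genes=tuple(sorted(universe)))
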