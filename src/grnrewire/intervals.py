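"""Genomic-interval operations on ATAC peak sets.

Peaks live in pandas DataFrames with at least ``chrom``, ``start``, ``end``
columns (0-based half-open, the BED convention) and optional ``name`` and
``summit`` columns.  Within each chromosome intervals must be sorted by
start; operations that require sortedness raise rather than silently
re-sorting, so that provenance of the input ordering is never hidden.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PEAK_COLUMNS = ("chrom", "start", "end")


def _validate_peaks(peaks: pd.DataFrame, name: str = "peaks") -> None:
    for col in PEAK_COLUMNS:
        if col not in peaks.columns:
            raise ValueError(f"{name} is missing required column {col!r}")
    if len(peaks) and not (peaks["start"] < peaks["end"]).all():
        raise ValueError(f"{name} contains intervals with start >= end")


def _check_sorted(peaks: pd.DataFrame, name: str) -> None:
    for chrom, sub in peaks.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise ValueError(
                f"{name} is not sorted by start within chromosome {chrom}; "
                "sort explicitly before calling"
            )


def _merge_sorted(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping [start, end) rows of a start-sorted (n, 2) array."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    merged = [intervals[0].tolist()]
    for s, e in intervals[1:]:
        if s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def reproducible_peaks(
    rep_a: pd.DataFrame, rep_b: pd.DataFrame, min_overlap: float = 0.5
) -> pd.DataFrame:
    """Keep peaks reproduced across two biological replicates.

    A pair of peaks (one per replicate) qualifies when their overlap length
    is at least ``min_overlap`` of the *shorter* peak.  Each qualifying pair
    is merged to its union interval, and chains of qualifying pairs merge
    into a single maximal interval.

    Parameters
    ----------
    rep_a, rep_b
        Peak tables sorted by start within each chromosome.
    min_overlap
        Required overlap as a fraction of the shorter peak, in (0, 1].

    Returns
    -------
    DataFrame with ``chrom``, ``start``, ``end`` of reproducible intervals.
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    _validate_peaks(rep_a, "rep_a")
    _validate_peaks(rep_b, "rep_b")
    _check_sorted(rep_a, "rep_a")
    _check_sorted(rep_b, "rep_b")

    out = []
    chroms = sorted(set(rep_a["chrom"]).intersection(rep_b["chrom"]))
    for chrom in chroms:
        a = rep_a.loc[rep_a["chrom"] == chrom, ["start", "end"]].to_numpy()
        b = rep_b.loc[rep_b["chrom"] == chrom, ["start", "end"]].to_numpy()
        pairs = []
        j0 = 0
        for s1, e1 in a:
            j = j0
            while j < len(b) and b[j, 1] <= s1:
                j += 1
            j0 = j
            while j < len(b) and b[j, 0] < e1:
                s2, e2 = b[j]
                ov = min(e1, e2) - max(s1, s2)
                shorter = min(e1 - s1, e2 - s2)
                if ov >= min_overlap * shorter:
                    pairs.append((min(s1, s2), max(e1, e2)))
                j += 1
        if pairs:
            pairs = np.asarray(sorted(pairs))
            for s, e in _merge_sorted(pairs):
                out.append((chrom, int(s), int(e)))
    return pd.DataFrame(out, columns=list(PEAK_COLUMNS))


def union_peaks(peaksets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of several peak sets, overlapping intervals merged maximally."""
    if not peaksets:
        raise ValueError("need at least one peak set")
    for i, ps in enumerate(peaksets):
        _validate_peaks(ps, f"peaksets[{i}]")
    pooled = pd.concat(
        [ps[list(PEAK_COLUMNS)] for ps in peaksets], ignore_index=True
    )
    out = []
    for chrom in sorted(pooled["chrom"].unique()):
        iv = pooled.loc[pooled["chrom"] == chrom, ["start", "end"]].to_numpy()
        iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
        for s, e in _merge_sorted(iv):
            out.append((chrom, int(s), int(e)))
    return pd.DataFrame(out, columns=list(PEAK_COLUMNS))


def annotate_peaks(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    gene_models: pd.DataFrame | None = None,
    tss_distance: int = 1_000,
    proximal_distance: int = 5_000,
) -> tuple[pd.Series, pd.Series]:
    """Classify peaks by genomic feature: TSS, proximal, genic or distal.

    The first matching category wins, in the order TSS (peak centre within
    ``tss_distance`` of a transcription start site), proximal (within
    ``proximal_distance``), genic (centre inside a gene body), distal
    (everything else).

    Parameters
    ----------
    tss
        DataFrame with ``gene``, ``chrom``, ``tss`` columns.
    gene_models
        Optional DataFrame with ``gene``, ``chrom``, ``start``, ``end``;
        without it no peak can be classified genic.

    Returns
    -------
    (categories, proportions)
        Per-peak category Series (aligned to ``peaks.index``) and the
        proportion of peaks per category.
    """
    _validate_peaks(peaks)
    if tss is None or len(tss) == 0:
        raise ValueError("TSS table must be nonempty")
    centres = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    cats = np.full(len(peaks), "distal", dtype=object)
    for chrom in peaks["chrom"].unique():
        sel = (peaks["chrom"] == chrom).to_numpy()
        c = centres[sel]
        t = np.sort(tss.loc[tss["chrom"] == chrom, "tss"].to_numpy())
        if len(t):
            idx = np.searchsorted(t, c)
            left = t[np.clip(idx - 1, 0, len(t) - 1)]
            right = t[np.clip(idx, 0, len(t) - 1)]
            dist = np.minimum(np.abs(c - left), np.abs(c - right))
        else:
            dist = np.full(len(c), np.inf)
        local = np.full(len(c), "distal", dtype=object)
        if gene_models is not None and len(gene_models):
            gm = gene_models[gene_models["chrom"] == chrom]
            inside = np.zeros(len(c), dtype=bool)
            for s, e in gm[["start", "end"]].to_numpy():
                inside |= (c >= s) & (c < e)
            local[inside] = "genic"
        local[dist <= proximal_distance] = "proximal"
        local[dist <= tss_distance] = "TSS"
        cats[sel] = local
    categories = pd.Series(cats, index=peaks.index, name="category")
    order = ["TSS", "proximal", "genic", "distal"]
    proportions = categories.value_counts(normalize=True).reindex(order, fill_value=0.0)
    return categories, proportions
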