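"""On-disk formats: BED6 peaks, FASTA, JASPAR PWMs, TSV tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_bed(peaks: pd.DataFrame, path) -> None:
    """Write peaks as BED6 (0-based half-open)."""
    df = peaks.copy()
    if "name" not in df.columns:
        df["name"] = [f"peak_{i:05d}" for i in range(len(df))]
    df["score"] = 0
    df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    return df


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_cell_metadata(adata, path) -> None:
    meta = adata.obs[["state", "pseudotime"]].copy()
    emb = np.asarray(adata.obsm["X_emb"])
    meta["emb_x"] = emb[:, 0]
    meta["emb_y"] = emb[:, 1]
    meta.index.name = "cell_id"
    write_tsv(meta, path)


def write_grid_field(field, path) -> None:
    """Dump a grid vector field as TSV (gx, gy, vx, vy, mass, mask)."""
    g = len(field.x)
    rows = []
    for i in range(g):
        for j in range(g):
            rows.append(
                (
                    field.x[i], field.y[j], field.vx[i, j], field.vy[i, j],
                    field.mass[i, j], int(field.mask[i, j]),
                )
            )
    pd.DataFrame(
        rows, columns=["gx", "gy", "vx", "vy", "mass", "mask"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
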