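"""Network topology statistics, cross-state overlap, and rewiring scores.

The rewiring score of a node between two state GRNs is the sum of absolute
changes in connectivity score (the signed edge coefficient) over all edges
incident to the node, with an absent edge counted as weight zero:

    score(i) = sum_j |W_A[i, j] - W_B[i, j]| + sum_j |W_A[j, i] - W_B[j, i]|

with the diagonal term counted once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grn import GRNResults


def degree_centrality(grn: GRNResults) -> pd.DataFrame:
    """Per-node in/out/total degree (unweighted and |coefficient|-weighted).

    Dense ranks (1 = highest) are reported for each statistic.
    """
    edges = grn.edges
    nodes = sorted(set(edges["regulator"]) | set(edges["target"]))
    out = pd.DataFrame(
        0.0,
        index=nodes,
        columns=[
            "out_degree", "in_degree", "total_degree",
            "weighted_out", "weighted_in", "weighted_total",
        ],
    )
    for reg, tgt, coef in edges[["regulator", "target", "coefficient"]].itertuples(
        index=False
    ):
        out.loc[reg, "out_degree"] += 1
        out.loc[tgt, "in_degree"] += 1
        out.loc[reg, "weighted_out"] += abs(coef)
        out.loc[tgt, "weighted_in"] += abs(coef)
    out["total_degree"] = out["out_degree"] + out["in_degree"]
    out["weighted_total"] = out["weighted_out"] + out["weighted_in"]
    for col in list(out.columns):
        out[f"{col}_rank"] = out[col].rank(method="dense", ascending=False).astype(int)
    return out


def network_overlap(grns: list[GRNResults]) -> dict:
    """Shared/unique nodes, TFs and edges across several state GRNs.

    A node is any gene incident to a kept edge; a TF is a node with at least
    one outgoing edge in at least one network; edge identity is the
    (regulator, target) pair ignoring the weight.
    """
    if len(grns) < 2:
        raise ValueError("need >= 2 networks")
    node_sets, edge_sets = {}, {}
    for g in grns:
        name = g.state
        node_sets[name] = set(g.edges["regulator"]) | set(g.edges["target"])
        edge_sets[name] = set(
            map(tuple, g.edges[["regulator", "target"]].itertuples(index=False))
        )
    all_tfs = set().union(*(set(g.edges["regulator"]) for g in grns))
    tf_sets = {name: nodes & all_tfs for name, nodes in node_sets.items()}

    def _report(sets: dict[str, set]) -> dict:
        union = set().union(*sets.values())
        shared = set.intersection(*sets.values())
        return {
            "union": len(union),
            "shared": len(shared),
            "shared_fraction": len(shared) / len(union) if union else 0.0,
            "per_network": {k: len(v) for k, v in sets.items()},
            "unique": {
                k: len(v - set().union(*(w for n, w in sets.items() if n != k)))
                for k, v in sets.items()
            },
        }

    return {
        "nodes": _report(node_sets),
        "tfs": _report(tf_sets),
        "edges": _report(edge_sets),
    }


def rewiring_score(
    grn_a: GRNResults, grn_b: GRNResults, use_absolute: bool = False
) -> pd.DataFrame:
    """Per-node rewiring score between two state GRNs.

    Adjacency matrices are taken over the union of both networks' node sets
    (missing edges weight 0).  ``use_absolute`` compares |coefficients|
    instead of signed coefficients.

    Returns a DataFrame indexed by node with ``rewiring_score`` and a dense
    ``rank`` (ties broken by name in the sort order).
    """
    nodes = tuple(
        sorted(
            set(grn_a.edges["regulator"]) | set(grn_a.edges["target"])
            | set(grn_b.edges["regulator"]) | set(grn_b.edges["target"])
        )
    )
    wa = grn_a.weight_matrix(nodes).to_numpy()
    wb = grn_b.weight_matrix(nodes).to_numpy()
    if use_absolute:
        wa, wb = np.abs(wa), np.abs(wb)
    diff = np.abs(wa - wb)
    score = diff.sum(axis=1) + diff.sum(axis=0) - np.diag(diff)
    table = pd.DataFrame({"rewiring_score": score}, index=list(nodes))
    table["rank"] = (
        table["rewiring_score"].rank(method="dense", ascending=False).astype(int)
    )
    return table.sort_index(kind="mergesort").sort_values("rank", kind="mergesort")


def top_rewired(table: pd.DataFrame, n: int = 50) -> pd.DataFrame:
    """Top-n rewired genes, deterministic ties by name."""
    ordered = table.sort_index(kind="mergesort").sort_values(
        "rewiring_score", ascending=False, kind="mergesort"
    )
    return ordered.head(n)
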