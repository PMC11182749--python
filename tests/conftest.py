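"""Shared fixtures: a small synthetic analysis and the full default one.

Everything is generated at runtime from seeds; no fixture files are stored.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from grnrewire import (
    GRNModel,
    GRNResults,
    PerturbationEngine,
    TrajectoryConfig,
    assign_peaks_to_genes,
    build_base_grn,
    scan_motifs,
    simulate_regulatory_genome,
    simulate_trajectory_dataset,
)


def make_grn(edges: list[tuple[str, str, float]], state: str = "test") -> GRNResults:
    """GRNResults from a plain (regulator, target, coefficient) edge list."""
    df = pd.DataFrame(edges, columns=["regulator", "target", "coefficient"])
    df["coefficient_std"] = df["coefficient"]
    df["stability"] = 1.0
    df["z"] = np.inf
    universe = tuple(sorted(set(df["regulator"]) | set(df["target"])))
    return GRNResults(
        state=state, edges=df, gene_universe=universe,
        n_cells=0, ridge_penalty=float("nan"), n_bags=0,
    )


def full_analysis(seed: int, **config_overrides) -> SimpleNamespace:
    """Simulate a dataset + genome, build the base GRN, fit the pooled GRN
    and set up the perturbation engine — the chain used by the acceptance
    criteria."""
    cfg = TrajectoryConfig(seed=seed, **config_overrides)
    adata, truth = simulate_trajectory_dataset(cfg)
    genome = simulate_regulatory_genome(truth, seed=seed)
    hits = scan_motifs(genome.sequences, genome.pwms)
    base = build_base_grn(
        assign_peaks_to_genes(genome.peaks, genome.tss),
        hits,
        genome.tf_motif_map,
        genes=list(adata.var_names),
    )
    grn = GRNModel(adata, base, state=None).fit(seed=seed)
    engine = PerturbationEngine(grn, adata, states=cfg.state_names)
    return SimpleNamespace(
        config=cfg, adata=adata, truth=truth, genome=genome,
        base=base, grn=grn, engine=engine,
    )


@pytest.fixture(scope="session")
def small():
    """A fast 400-cell, 8-TF, 40-target analysis for module tests."""
    return full_analysis(7, n_cells=400, n_tfs=8, n_targets=40)


@pytest.fixture(scope="session")
def default_analysis():
    """The default dataset of the acceptance criteria (1500 cells, 25 TFs,
    150 targets, seed 1)."""
    return full_analysis(1)


@pytest.fixture(scope="session")
def default_scores(default_analysis):
    """Perturbation-score table (all TFs, KO+OE) on the default dataset."""
    return default_analysis.engine.score_all()
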