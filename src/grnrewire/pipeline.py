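"""End-to-end pipeline: simulate -> atac -> base GRN -> state GRNs ->
topology/rewiring -> perturbation simulation -> signatures.

A single declarative configuration drives every stage; all outputs are
plain-text files under the output directory and a JSON manifest records the
stage sequence, per-stage seeds and SHA-256 checksums so that an unchanged
re-run is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .basegrn import assign_peaks_to_genes, build_base_grn
from .diffacc import moderated_differential_accessibility
from .grn import GRNModel, select_genes
from .motifs import scan_motifs, write_jaspar
from .perturb import PerturbationEngine, rank_tfs
from .signatures import (
    define_signature_from_de,
    rank_signature_score,
    regulator_signature,
    wilcoxon_de,
)
from .synthetic import (
    TrajectoryConfig,
    simulate_atac_counts,
    simulate_regulatory_genome,
    simulate_trajectory_dataset,
)
from .topology import degree_centrality, network_overlap, rewiring_score, top_rewired

log = logging.getLogger("grnrewire")

STAGES = (
    "simulate", "atac", "basegrn", "fit", "topology", "perturb", "signatures",
)


@dataclass
class PipelineConfig:
    """Declarative configuration for a full synthetic-data run."""

    out_dir: str = "grnrewire_out"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # TrajectoryConfig overrides
    k_topology: int = 2000
    k_simulation: int = 10_000
    n_hvg: int | None = None
    fc_threshold: float = 2.0
    padj_threshold: float = 0.01
    oe_multiplier: float = 1.5
    logfc_min: float = 0.5
    sig_padj_max: float = 0.05
    connectivity_min: float = 0.1
    signature_top_n: int = 10
    rewire_state_a: str = "PrP"
    rewire_state_b: str = "Non-RSP"

    def validate(self) -> None:
        if self.k_simulation < self.k_topology:
            raise ValueError(
                "constraint violated: k_simulation must be >= k_topology "
                f"(got {self.k_simulation} < {self.k_topology})"
            )
        if self.oe_multiplier < 1:
            raise ValueError("constraint violated: oe_multiplier must be >= 1")
        if not 0 < self.sig_padj_max <= 1 or not 0 < self.padj_threshold <= 1:
            raise ValueError("constraint violated: p thresholds must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed from the global seed by a fixed counter scheme."""
    return int((seed * 1000 + STAGES.index(stage)) % (2**31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": asdict(config)}
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "outputs": {f.name: _sha256(f) for f in sorted(files)},
        }
        log.info("stage=%s seed=%d complete (%d files)",
                 stage, stage_seed(config.seed, stage), len(files))

    try:
        # --- simulate -----------------------------------------------------
        sim_seed = stage_seed(config.seed, "simulate")
        traj = TrajectoryConfig(seed=sim_seed, **config.simulate)
        adata, truth = simulate_trajectory_dataset(traj)
        genome = simulate_regulatory_genome(truth, seed=sim_seed)
        density, planted = simulate_atac_counts(
            n_peaks=2000, seed=sim_seed
        )
        files = []
        expr_path = out / "expression_counts.tsv"
        pd.DataFrame(
            np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
        ).to_csv(expr_path, sep="\t", float_format="%.6g")
        files.append(expr_path)
        gio.write_cell_metadata(adata, out / "cell_metadata.tsv")
        files.append(out / "cell_metadata.tsv")
        gio.write_bed(genome.peaks, out / "peaks.bed")
        files.append(out / "peaks.bed")
        gio.write_tsv(genome.tss.set_index("gene"), out / "tss.tsv")
        files.append(out / "tss.tsv")
        gio.write_fasta(genome.sequences, out / "peak_sequences.fa")
        files.append(out / "peak_sequences.fa")
        write_jaspar(genome.pwms, out / "motifs.jaspar")
        files.append(out / "motifs.jaspar")
        gio.write_tsv(genome.tf_motif_map.set_index("tf"), out / "tf_motif_map.tsv")
        files.append(out / "tf_motif_map.tsv")
        gio.write_tsv(
            truth.pooled_coefficients(), out / "planted_coefficients.tsv"
        )
        files.append(out / "planted_coefficients.tsv")
        record("simulate", files)

        # --- atac ---------------------------------------------------------
        da = moderated_differential_accessibility(
            density,
            [c.rsplit("_", 1)[0] for c in density.columns],
            fc_threshold=config.fc_threshold,
            padj_threshold=config.padj_threshold,
        )
        gio.write_tsv(da, out / "differential_accessibility.tsv")
        record("atac", [out / "differential_accessibility.tsv"])

        # --- base GRN -----------------------------------------------------
        peak2gene = assign_peaks_to_genes(genome.peaks, genome.tss)
        hits = scan_motifs(genome.sequences, genome.pwms)
        base = build_base_grn(
            peak2gene, hits, genome.tf_motif_map, genes=list(adata.var_names)
        )
        gio.write_tsv(base.pairs, out / "base_grn_pairs.tsv", index=False)
        record("basegrn", [out / "base_grn_pairs.tsv"])

        # --- fit ----------------------------------------------------------
        fit_seed = stage_seed(config.seed, "fit")
        n_hvg = config.n_hvg or adata.n_vars
        genes = select_genes(adata, n_hvg=min(n_hvg, adata.n_vars))
        universe = sorted((set(genes) & set(base.genes)) | set(base.tfs))
        state_grns = {}
        fit_files = []
        for state in traj.state_names:
            res = GRNModel(adata, base, state=state, genes=universe).fit(seed=fit_seed)
            state_grns[state] = res.prune(config.k_topology)
            path = out / f"grn_{state.replace('/', '_')}.tsv"
            gio.write_tsv(state_grns[state].edges, path, index=False)
            fit_files.append(path)
        pooled = GRNModel(adata, base, state=None, genes=universe).fit(seed=fit_seed)
        pooled = pooled.prune(config.k_simulation)
        gio.write_tsv(pooled.edges, out / "grn_all.tsv", index=False)
        fit_files.append(out / "grn_all.tsv")
        record("fit", fit_files)

        # --- topology -----------------------------------------------------
        topo_files = []
        for state, res in state_grns.items():
            path = out / f"topology_{state.replace('/', '_')}.tsv"
            gio.write_tsv(degree_centrality(res), path)
            topo_files.append(path)
        overlap = network_overlap(list(state_grns.values()))
        (out / "network_overlap.json").write_text(json.dumps(overlap, indent=2))
        topo_files.append(out / "network_overlap.json")
        rewired = rewiring_score(
            state_grns[config.rewire_state_a], state_grns[config.rewire_state_b]
        )
        gio.write_tsv(top_rewired(rewired, 50), out / "rewiring_top50.tsv")
        gio.write_tsv(rewired, out / "rewiring_scores.tsv")
        topo_files += [out / "rewiring_top50.tsv", out / "rewiring_scores.tsv"]
        record("topology", topo_files)

        # --- perturb --------------------------------------------------------
        engine = PerturbationEngine(
            pooled, adata, edge_budget=config.k_simulation,
            states=traj.state_names,
        )
        scores = engine.score_all()
        gio.write_tsv(scores, out / "perturbation_scores.tsv", index=False)
        classified = rank_tfs(scores)
        gio.write_tsv(classified, out / "tf_classification.tsv", index=False)
        record("perturb", [out / "perturbation_scores.tsv", out / "tf_classification.tsv"])

        # --- signatures -----------------------------------------------------
        de = wilcoxon_de(adata, config.rewire_state_a, config.rewire_state_b)
        gio.write_tsv(de, out / "de_prp_vs_nonrsp.tsv")
        sig_files = [out / "de_prp_vs_nonrsp.tsv"]
        prp_sig = define_signature_from_de(
            de, name="PrP_signature",
            logfc_min=config.logfc_min, padj_max=config.sig_padj_max,
        )
        pos_sig = regulator_signature(
            scores, state_grns[config.rewire_state_a],
            polarity="positive", top_n=config.signature_top_n,
            connectivity_min=config.connectivity_min,
        )
        sigs = {"PrP_signature": prp_sig, "positive_regulators": pos_sig}
        (out / "signatures.json").write_text(
            json.dumps({k: list(v.genes) for k, v in sigs.items()}, indent=2)
        )
        sig_files.append(out / "signatures.json")
        r_max = min(1500, adata.n_vars - 1)
        score_df = pd.DataFrame(
            {k: rank_signature_score(adata, v, r_max=r_max) for k, v in sigs.items()}
        )
        gio.write_tsv(score_df, out / "signature_scores.tsv")
        sig_files.append(out / "signature_scores.tsv")
        record("signatures", sig_files)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        log.error("pipeline failed: %s", exc)
        raise

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
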