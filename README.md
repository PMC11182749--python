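# grnrewire

State-specific gene regulatory network (GRN) inference, rewiring statistics and
in-silico transcription-factor perturbation for vascular smooth muscle cell
(VSMC) phenotype switching.

After arterial injury, medial VSMCs de-differentiate and traverse a trajectory
of transitional states before a minority re-differentiates. `grnrewire`
implements the computational chain used to dissect which transcription factors
(TFs) drive or block that transition:

1. **ATAC peaks** — replicate-reproducible peak filtering, union peak lists,
   genomic annotation, and moderated-*t* differential accessibility
   (empirical-Bayes variance shrinkage, Benjamini–Hochberg correction).
2. **Base GRN** — candidate TF→target pairs from motif hits (log-odds PWM
   scan, both strands) inside accessible peaks assigned to their nearest TSS.
3. **State GRNs** — signed, weighted networks per cell state by bagged ridge
   regression of each target on its candidate TFs, with stability and
   jackknife-*z* filters (`GRNModel(...).fit() -> GRNResults`,
   statsmodels-style).
4. **Topology & rewiring** — degree centrality, cross-state edge overlap, and
   a per-gene rewiring score (sum of absolute connectivity change between two
   states).
5. **Perturbation simulation** — in-silico TF knockout (KO, expression → 0)
   and overexpression (OE, → 1.5 × max), delta propagation through the GRN,
   a transition-probability vector field on an embedding grid, and a
   perturbation score (PS): the inner product of the normalised simulation
   and developmental-flow vectors. `rank_tfs` classifies TFs as stimulators,
   blockers, or context-specific.
6. **Signatures** — Wilcoxon/Mann–Whitney differential expression, state and
   regulator signatures, and a capped rank-based (UCell-style) per-cell
   signature score.
7. **Synthetic data** — a trajectory simulator with planted GRN ground truth
   (TF ramps, signed coefficients, regulatory genome with planted motifs,
   ATAC count matrices with planted fold changes) used by the test suite; no
   fixture files are stored.

## Worked example

Everything below is generated from a seed at runtime (400 cells, 8 TFs,
40 targets; ~5 s):

```python
from grnrewire import (
    TrajectoryConfig, simulate_trajectory_dataset, simulate_regulatory_genome,
    scan_motifs, assign_peaks_to_genes, build_base_grn, GRNModel,
    PerturbationEngine, rank_tfs,
)

cfg = TrajectoryConfig(n_cells=400, n_tfs=8, n_targets=40, seed=7)
adata, truth = simulate_trajectory_dataset(cfg)

genome = simulate_regulatory_genome(truth, seed=7)
hits = scan_motifs(genome.sequences, genome.pwms)
base = build_base_grn(
    assign_peaks_to_genes(genome.peaks, genome.tss),
    hits, genome.tf_motif_map, genes=list(adata.var_names),
)

grn = GRNModel(adata, base, state=None).fit(seed=7)
print(grn.summary())
```

```
GRN fit for state 'all'
  cells: 400   bags: 20   ridge penalty: 31.62
  edges kept: 45   regulators: 8   targets: 28
  strongest edges (connectivity score):
          TF06 -> G000       -1.0122 (stability 1.00)
          TF06 -> G021       -0.7614 (stability 1.00)
          TF01 -> G033       +0.7537 (stability 1.00)
          ...
```

```python
engine = PerturbationEngine(grn, adata, states=cfg.state_names)
print(rank_tfs(engine.score_all()).head(4).to_string(index=False))
```

```
  tf  ko_sum_negative  ko_sum_positive            class
TF05      -134.097663         0.000000       stimulator
TF04      -120.862981         0.082751       stimulator
TF00       -80.266585        20.246535 context-specific
TF03       -79.847559        54.862763 context-specific
```

The ranking by negative KO score puts trajectory-driving TFs first; see
`docs/methods.md` for how the PS scale and the classification thresholds
behave (including a structural artifact of the correlation-based vector field
that affects the *labels*, but not the *ranking*, of early-saturating
stimulators).

## Command line

```bash
grnrewire simulate --seed 5 --out sim/             # write synthetic inputs
grnrewire atac reproducible --rep-a a.bed --rep-b b.bed --out rep.bed
grnrewire atac union a.bed b.bed --out union.bed
grnrewire atac da --density density.tsv --groups c,c,i,i --out da.tsv
grnrewire basegrn --peaks peaks.bed --fasta seqs.fa --pwms motifs.jaspar \
    --tss tss.tsv --tf-map tf_motif_map.tsv --out base.tsv
grnrewire rewire --a PrP --b Non-RSP --grn-a a.tsv --grn-b b.tsv --out rw.tsv
grnrewire run config.yaml                          # full staged pipeline
```

`grnrewire run` executes the seven pipeline stages (simulate → peaks → base
GRN → state GRNs → topology → perturbation → signatures), writing per-stage
outputs and a SHA-256 manifest; reruns with the same config reproduce
identical checksums.

## Tests and reproducing the headline numbers

```bash
python -m pytest            # ~90 s single-core; 191 tests + 2 strict xfails
python scripts/acceptance.py --seed 1 --out results/acceptance.json  # ~70 s
```

The acceptance script writes JSON with the headline quantities
(`ko_oe_r2`, `edge_auprc`, `sign_agreement_pct`, `null_edge_pct`,
`flow_angular_error_deg`, `stimulator_recovery_seeds`,
`blocker_recovery_seeds`, `blocker_rule_tf_recovery`,
`rank_separation_seeds`, `da_type1_error_pct`, `da_sensitivity_pct`), each as
`{"value": v, "n": size}`. All quantities are computed from synthetic data
generated at the given seed.

## Layout

```
src/grnrewire/
  intervals.py    peak reproducibility, union, annotation
  motifs.py       PWMs, JASPAR I/O, log-odds scanning
  diffacc.py      moderated-t differential accessibility
  basegrn.py      peak→gene assignment, base GRN construction
  grn.py          GRNModel / GRNResults (bagged ridge state GRNs)
  topology.py     degrees, overlap, rewiring scores
  perturb.py      KO/OE simulation, vector fields, flow, PS, rank_tfs
  signatures.py   DE, signature definition, rank scoring
  synthetic.py    trajectory/genome/ATAC generators with planted truth
  pipeline.py     staged pipeline with manifest
  io.py, cli.py   on-disk formats and the `grnrewire` CLI
docs/methods.md   model, defaults, numerical choices, known artifacts
```
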