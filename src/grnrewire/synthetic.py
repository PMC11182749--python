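"""Synthetic trajectory, regulatory-genome and ATAC-count generators.

These generators plant a fully known ground truth — a signed TF -> target
coefficient matrix per cell state, TF expression programs along pseudotime,
motif occurrences in peaks assigned to targets, and differential peak
accessibility — so that every downstream stage (base-GRN construction, GRN
fitting, rewiring, perturbation simulation, signature scoring) can be tested
against the planted answer without any external data.

The emulated system is a four-state vascular smooth-muscle-cell injury
trajectory (Non-RSP -> LNK -> PrP -> CYC): cells are placed uniformly along
a pseudotime axis, "stimulator" TFs ramp up along the trajectory and drive
their targets positively, "repressor" TFs ramp down and carry negative
coefficients, and a contractile root marker (Myh11 analogue) is high at the
trajectory root.  The 2-D embedding is (pseudotime, noise), so the true
developmental flow is analytically (1, 0) everywhere.

Randomness is organised into named substreams of the user seed so that
individual draws (e.g. the Bernoulli edge mask) can be re-enumerated
independently: substream k is ``numpy.random.default_rng(
numpy.random.SeedSequence([seed, k]))`` with k = 0 edges, 1 TF profiles,
2 cells (pseudotime, embedding), 3 expression noise, 4 count sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .motifs import PWM, reverse_complement

DEFAULT_STATES = (("Non-RSP", 0.25), ("LNK", 0.5), ("PrP", 0.75), ("CYC", 1.0))
ROOT_MARKER = "Myh11"

_EDGE_STREAM, _PROFILE_STREAM, _CELL_STREAM, _NOISE_STREAM, _COUNT_STREAM = range(5)


def _stream(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(k)]))


@dataclass
class TrajectoryConfig:
    """Study conditions for the synthetic injury trajectory."""

    n_cells: int = 1500
    n_tfs: int = 25
    n_targets: int = 150
    states: tuple[tuple[str, float], ...] = DEFAULT_STATES
    edge_density: float = 0.1
    coeff_scale: float = 1.0
    noise_sd: float = 0.3
    depth_mean: float = 50.0
    seed: int = 0
    stimulator_fraction: float = 0.7
    emb_noise_sd: float = 0.2
    depth_sigma: float = 0.3
    overdispersion: float | None = None
    rewire_fraction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_tfs, self.n_targets) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if self.noise_sd < 0 or self.coeff_scale <= 0 or self.depth_mean <= 0:
            raise ValueError("noise_sd >= 0, coeff_scale > 0, depth_mean > 0 required")
        bounds = [b for _, b in self.states]
        if sorted(bounds) != bounds or bounds[-1] != 1.0 or min(bounds) <= 0:
            raise ValueError("state quantile boundaries must increase and end at 1.0")
        if self.n_cells < 4 * len(self.states):
            raise ValueError(
                f"n_cells={self.n_cells} cannot populate {len(self.states)} states "
                "(need >= 4 cells per state)"
            )

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.states)

    @property
    def tf_names(self) -> tuple[str, ...]:
        return tuple(f"TF{i:02d}" for i in range(self.n_tfs))

    @property
    def target_names(self) -> tuple[str, ...]:
        return tuple(f"G{i:03d}" for i in range(self.n_targets))


@dataclass
class PlantedTruth:
    """Ground truth planted by the trajectory generator."""

    coefficients: dict[str, pd.DataFrame]  # state -> (targets x TFs) signed matrix
    tf_params: pd.DataFrame  # per TF: lo, hi, midpoint, direction (+1 up, -1 down)
    stimulator_tfs: tuple[str, ...]
    repressor_tfs: tuple[str, ...]
    root_marker: str = ROOT_MARKER
    state_names: tuple[str, ...] = field(default_factory=tuple)

    def tf_profile(self, tf: str, t: np.ndarray) -> np.ndarray:
        """Noise-free logistic expression program of one TF over pseudotime."""
        row = self.tf_params.loc[tf]
        z = row["direction"] * (np.asarray(t, dtype=float) - row["midpoint"]) / 0.1
        return row["lo"] + (row["hi"] - row["lo"]) / (1.0 + np.exp(-z))

    def edge_set(self) -> set[tuple[str, str]]:
        """(TF, target) pairs with a nonzero coefficient in any state."""
        pairs: set[tuple[str, str]] = set()
        for mat in self.coefficients.values():
            nz = np.nonzero(mat.to_numpy())
            pairs.update(
                (mat.columns[j], mat.index[i]) for i, j in zip(*nz)
            )
        return pairs

    def pooled_coefficients(self) -> pd.DataFrame:
        """Across-state mean coefficient matrix (targets x TFs)."""
        mats = list(self.coefficients.values())
        return sum(mats[1:], mats[0].copy()) / len(mats)


def _logistic_params(config: TrajectoryConfig) -> pd.DataFrame:
    rng = _stream(config.seed, _PROFILE_STREAM)
    n_stim = int(round(config.stimulator_fraction * config.n_tfs))
    n_stim = min(max(n_stim, 1), config.n_tfs)
    rows = []
    for i, tf in enumerate(config.tf_names):
        direction = 1.0 if i < n_stim else -1.0
        midpoint = rng.uniform(0.2, 0.8)
        rows.append((tf, 0.2, 2.0, midpoint, direction))
    return pd.DataFrame(
        rows, columns=["tf", "lo", "hi", "midpoint", "direction"]
    ).set_index("tf")


def _planted_coefficients(config: TrajectoryConfig, tf_params: pd.DataFrame):
    """Bernoulli edge mask then row-major magnitude draws (substream 0)."""
    rng = _stream(config.seed, _EDGE_STREAM)
    mask = rng.random((config.n_targets, config.n_tfs)) < config.edge_density
    magnitudes = rng.uniform(0.5, 1.5, size=int(mask.sum())) * config.coeff_scale
    signs = tf_params["direction"].to_numpy()
    w = np.zeros((config.n_targets, config.n_tfs))
    w[mask] = magnitudes
    w *= signs[None, :]
    base = pd.DataFrame(w, index=config.target_names, columns=config.tf_names)

    coeffs = {name: base.copy() for name in config.state_names}
    if config.rewire_fraction > 0:
        # rewired edges are absent in the first half of states, present later
        flat = np.flatnonzero(mask)
        n_rewire = int(round(config.rewire_fraction * len(flat)))
        chosen = rng.choice(flat, size=n_rewire, replace=False)
        half = len(config.state_names) // 2
        for name in config.state_names[:half]:
            m = coeffs[name].to_numpy()
            m.flat[chosen] = 0.0
            coeffs[name] = pd.DataFrame(
                m, index=config.target_names, columns=config.tf_names
            )
    return coeffs, mask


def simulate_trajectory_dataset(
    config: TrajectoryConfig,
) -> tuple[ad.AnnData, PlantedTruth]:
    """Generate a trajectory-structured single-cell dataset with known truth.

    Returns an AnnData (``X`` raw counts; layers ``expression`` for the
    pre-count continuous values and ``lognorm`` for depth-scaled log1p
    counts; ``obs`` state / pseudotime; ``obsm['X_emb']`` the 2-D embedding)
    and the :class:`PlantedTruth`.
    """
    tf_params = _logistic_params(config)
    coeffs, _ = _planted_coefficients(config, tf_params)
    n_stim = int((tf_params["direction"] > 0).sum())
    truth = PlantedTruth(
        coefficients=coeffs,
        tf_params=tf_params,
        stimulator_tfs=config.tf_names[:n_stim],
        repressor_tfs=config.tf_names[n_stim:],
        state_names=config.state_names,
    )

    rng_cells = _stream(config.seed, _CELL_STREAM)
    rng_noise = _stream(config.seed, _NOISE_STREAM)
    rng_counts = _stream(config.seed, _COUNT_STREAM)

    t = rng_cells.uniform(0.0, 1.0, size=config.n_cells)
    emb = np.column_stack(
        [t, rng_cells.normal(0.0, config.emb_noise_sd, size=config.n_cells)]
    )
    # state labels from empirical pseudotime quantiles
    bounds = np.array([b for _, b in config.states])
    cuts = np.quantile(t, bounds[:-1])
    state_idx = np.searchsorted(cuts, t, side="right")
    states = np.array(config.state_names, dtype=object)[state_idx]

    tf_expr = np.column_stack(
        [truth.tf_profile(tf, t) for tf in config.tf_names]
    )
    tf_expr = np.maximum(
        tf_expr + rng_noise.normal(0.0, config.noise_sd, size=tf_expr.shape), 0.0
    )

    # per-target baseline offset keeps the noise-free mean nonnegative and is
    # zero whenever the planted combination already is (pure-positive case)
    grid = np.linspace(0.0, 1.0, 101)
    profile_grid = np.column_stack(
        [truth.tf_profile(tf, grid) for tf in config.tf_names]
    )
    target_expr = np.zeros((config.n_cells, config.n_targets))
    offsets = {}
    for s_i, state in enumerate(config.state_names):
        w = coeffs[state].to_numpy()  # targets x TFs
        offsets[state] = np.maximum(0.0, -(profile_grid @ w.T).min(axis=0))
        in_state = state_idx == s_i
        target_expr[in_state] = tf_expr[in_state] @ w.T + offsets[state][None, :]
    target_expr = np.maximum(
        target_expr + rng_noise.normal(0.0, config.noise_sd, size=target_expr.shape),
        0.0,
    )

    root_expr = np.maximum(
        0.2 + 1.8 / (1.0 + np.exp((t - 0.25) / 0.08))
        + rng_noise.normal(0.0, config.noise_sd, size=config.n_cells),
        0.0,
    )

    expr = np.column_stack([tf_expr, target_expr, root_expr])
    genes = list(config.tf_names) + list(config.target_names) + [ROOT_MARKER]

    depth = rng_counts.lognormal(
        np.log(config.depth_mean), config.depth_sigma, size=config.n_cells
    )
    lam = depth[:, None] * expr
    if config.overdispersion:
        # gamma-Poisson mixture: unit-mean gamma with variance = overdispersion
        shape = 1.0 / config.overdispersion
        lam = lam * rng_counts.gamma(shape, 1.0 / shape, size=lam.shape)
    counts = rng_counts.poisson(lam).astype(np.float64)

    totals = counts.sum(axis=1)
    totals[totals == 0] = 1.0
    lognorm = np.log1p(counts / totals[:, None] * np.median(totals))

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {
                "state": pd.Categorical(states, categories=config.state_names),
                "pseudotime": t,
            },
            index=[f"cell_{i:04d}" for i in range(config.n_cells)],
        ),
        var=pd.DataFrame(
            {
                "is_tf": [g in config.tf_names for g in genes],
                "role": (
                    ["tf"] * config.n_tfs
                    + ["target"] * config.n_targets
                    + ["root_marker"]
                ),
            },
            index=genes,
        ),
    )
    adata.layers["expression"] = expr
    adata.layers["lognorm"] = lognorm
    adata.obsm["X_emb"] = emb
    return adata, truth


# ---------------------------------------------------------------------------
# regulatory genome
# ---------------------------------------------------------------------------

@dataclass
class RegulatoryGenome:
    """Synthetic peak universe with planted motif occurrences."""

    peaks: pd.DataFrame  # chrom, start, end, name (sorted)
    tss: pd.DataFrame  # gene, chrom, tss, strand
    pwms: list[PWM]
    sequences: dict[str, str]  # peak name -> sequence
    tf_motif_map: pd.DataFrame  # tf, motif_id
    chrom: str = "chrS"
    chrom_length: int = 0


def _random_consensus_set(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Distinct consensus k-mers, none equal to another's reverse complement."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if c in seen or reverse_complement(c) in seen or c == reverse_complement(c):
            continue
        out.append(c)
        seen.add(c)
        seen.add(reverse_complement(c))
    return out


def _scrub_background(
    seq: list[str], protected: list[tuple[int, int]], consensi: list[str],
    rng: np.random.Generator,
) -> None:
    """Re-randomise accidental consensus matches outside protected spans."""
    prot = np.zeros(len(seq), dtype=bool)
    for s, e in protected:
        prot[s:e] = True
    patterns = set(consensi) | {reverse_complement(c) for c in consensi}
    length = len(consensi[0])
    for _ in range(100):
        text = "".join(seq)
        dirty = False
        for pat in patterns:
            start = text.find(pat)
            while start != -1:
                span = range(start, start + length)
                free = [i for i in span if not prot[i]]
                if free:
                    dirty = True
                    for i in free:
                        seq[i] = "ACGT"[rng.integers(0, 4)]
                start = text.find(pat, start + 1)
        if not dirty:
            return
    raise RuntimeError("could not scrub background sequence of accidental motifs")


def simulate_regulatory_genome(
    truth: PlantedTruth,
    seed: int = 0,
    decoy_tf_rate: float = 5.0,
    decoy_peak_rate: float = 0.2,
    peak_width: int = 500,
    motif_length: int = 10,
    consensus_weight: float = 0.85,
    tss_spacing: int = 10_000,
) -> RegulatoryGenome:
    """Realise planted TF -> target edges as motif occurrences in peaks.

    Every planted edge gets at least one deliberately embedded consensus of
    the TF's motif inside a peak whose nearest TSS is the target gene.
    ``decoy_tf_rate`` adds Poisson-many motifs of non-regulator TFs per
    target; ``decoy_peak_rate`` adds motif-free peaks in a gene desert.
    Background sequence is rejection-sampled to contain no accidental
    consensus occurrence, so at zero decoy rates the downstream base GRN
    equals the planted incidence exactly.
    """
    if not truth.edge_set():
        raise ValueError("planted truth has no edges")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10]))

    tfs = list(truth.tf_params.index)
    targets = list(next(iter(truth.coefficients.values())).index)
    genes = tfs + targets + [truth.root_marker]

    tss_positions = {g: 50_000 + i * tss_spacing for i, g in enumerate(genes)}
    if len(set(tss_positions.values())) != len(genes):
        raise ValueError("two TSS coincide; nearest-gene assignment is ambiguous")
    tss = pd.DataFrame(
        {
            "gene": genes,
            "chrom": "chrS",
            "tss": [tss_positions[g] for g in genes],
            "strand": "+",
        }
    )

    consensi = _random_consensus_set(rng, len(tfs), motif_length)
    other = (1.0 - consensus_weight) / 3.0
    pwms = []
    for tf, cons in zip(tfs, consensi):
        counts = np.full((motif_length, 4), other * 100)
        for i, base in enumerate(cons):
            counts[i, "ACGT".index(base)] = consensus_weight * 100
        pwms.append(PWM.from_counts(f"M_{tf}", (tf,), counts))
    cons_by_tf = dict(zip(tfs, consensi))
    tf_motif_map = pd.DataFrame({"tf": tfs, "motif_id": [p.motif_id for p in pwms]})

    regulators_of: dict[str, list[str]] = {g: [] for g in targets}
    for tf, target in sorted(truth.edge_set()):
        regulators_of[target].append(tf)

    peak_rows = []
    sequences: dict[str, str] = {}
    sites_per_peak = 6
    peak_counter = 0
    for target in targets:
        sites = list(regulators_of[target])
        if decoy_tf_rate > 0:
            non_reg = [t for t in tfs if t not in sites]
            n_decoy = min(int(rng.poisson(decoy_tf_rate)), len(non_reg))
            if n_decoy:
                sites += sorted(rng.choice(non_reg, size=n_decoy, replace=False))
        n_peaks = max(1, int(np.ceil(len(sites) / sites_per_peak)))
        tss_pos = tss_positions[target]
        for k in range(n_peaks):
            side = 1 if k % 2 == 0 else -1
            offset = side * 600 * (k // 2 + 1)
            start = tss_pos + offset - peak_width // 2
            name = f"peak_{peak_counter:05d}"
            peak_counter += 1
            seq = ["ACGT"[i] for i in rng.integers(0, 4, size=peak_width)]
            protected = []
            for j, tf in enumerate(sites[k * sites_per_peak : (k + 1) * sites_per_peak]):
                pos = 20 + 70 * j
                cons = cons_by_tf[tf]
                if rng.random() < 0.5:
                    cons = reverse_complement(cons)
                seq[pos : pos + motif_length] = list(cons)
                protected.append((pos, pos + motif_length))
            _scrub_background(seq, protected, consensi, rng)
            peak_rows.append(("chrS", start, start + peak_width, name))
            sequences[name] = "".join(seq)

    desert_start = 50_000 + len(genes) * tss_spacing + 200_000
    n_decoy_peaks = int(round(decoy_peak_rate * peak_counter))
    for k in range(n_decoy_peaks):
        start = desert_start + k * 2_000
        name = f"peak_{peak_counter:05d}"
        peak_counter += 1
        seq = ["ACGT"[i] for i in rng.integers(0, 4, size=peak_width)]
        _scrub_background(seq, [], consensi, rng)
        peak_rows.append(("chrS", start, start + peak_width, name))
        sequences[name] = "".join(seq)

    peaks = (
        pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name"])
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    chrom_length = int(peaks["end"].max() + 10_000)
    return RegulatoryGenome(
        peaks=peaks,
        tss=tss,
        pwms=pwms,
        sequences=sequences,
        tf_motif_map=tf_motif_map,
        chrom_length=chrom_length,
    )


# ---------------------------------------------------------------------------
# ATAC read densities
# ---------------------------------------------------------------------------

def simulate_atac_counts(
    n_peaks: int,
    groups: tuple[str, str] = ("control", "injured"),
    planted_fc: float = 4.0,
    planted_fraction: float = 0.05,
    replicates: int = 2,
    noise_sd: float = 0.25,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-peak read densities for two conditions with planted fold changes.

    log2 intensities are Normal(group mean, noise_sd); a ``planted_fraction``
    of peaks carry a +log2(planted_fc) offset in the second group.  Densities
    are returned on a 2^x - 1 scale so that the differential-accessibility
    module's log2(d + 1) transform recovers the planted log intensities
    exactly (a noise-free 4-fold peak has logFC exactly 2).

    Returns the density matrix (peaks x samples) and a boolean Series
    marking planted peaks.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates per group")
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 20]))
    base = rng.normal(baseline_mean, baseline_sd, size=n_peaks)
    n_planted = int(round(planted_fraction * n_peaks))
    planted_idx = rng.choice(n_peaks, size=n_planted, replace=False)
    planted = np.zeros(n_peaks, dtype=bool)
    planted[planted_idx] = True
    shift = np.where(planted, np.log2(planted_fc), 0.0)

    cols, data = [], []
    for g_i, group in enumerate(groups):
        mean = base + (shift if g_i == 1 else 0.0)
        for r in range(replicates):
            cols.append(f"{group}_rep{r + 1}")
            logval = mean + rng.normal(0.0, noise_sd, size=n_peaks)
            data.append(np.maximum(2.0 ** logval - 1.0, 0.0))
    index = pd.Index([f"peak_{i:05d}" for i in range(n_peaks)], name="peak")
    density = pd.DataFrame(np.column_stack(data), index=index, columns=cols)
    return density, pd.Series(planted, index=index, name="planted")
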