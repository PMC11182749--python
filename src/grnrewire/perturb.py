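"""In-silico TF knockout/overexpression and perturbation-score ranking.

A perturbation fixes one TF's expression (0 for knockout; 1.5x its observed
maximum for overexpression) and propagates the change through the fitted GRN
for a small number of regulatory hops, clipping implied expression at zero
after every hop.  The per-cell expression shift is projected into the 2-D
embedding as a "simulation vector field": each cell's shift is correlated
with the expression differences to its embedding neighbours, the
correlations softmax-weight a local transition distribution, and the
density-corrected expected displacement gives the cell vector; cell vectors
are smoothed onto a regular grid with a Gaussian kernel.

The developmental flow is the gradient of grid-smoothed pseudotime.  The
perturbation score (PS) at each valid grid point is the inner product of the
L2-normalised simulation and flow vectors; TFs are ranked by the sums of
positive and negative PS, and classified as trajectory stimulators or
blockers with the knockout-score thresholds used throughout the analysis
(stimulator: negative KO score < -1 and positive KO score < 0.75; blocker:
positive KO score > 1).
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .grn import GRNResults


@dataclass
class PerturbationSpec:
    """One TF perturbation: knockout (0) or overexpression (1.5x max)."""

    tf: str
    mode: str = "KO"
    n_steps: int = 3
    edge_budget: int = 10_000
    oe_multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.mode not in ("KO", "OE"):
            raise ValueError("mode must be 'KO' or 'OE'")
        if self.n_steps < 1 or self.edge_budget < 1:
            raise ValueError("n_steps and edge_budget must be >= 1")


@dataclass
class GridField:
    """2-D vector field on a regular embedding grid."""

    x: np.ndarray  # (g,)
    y: np.ndarray  # (g,)
    vx: np.ndarray  # (g, g), [i, j] at (x[i], y[j])
    vy: np.ndarray
    mass: np.ndarray
    mask: np.ndarray  # bool, valid grid points

    @property
    def vectors(self) -> np.ndarray:
        return np.stack([self.vx, self.vy], axis=-1)

    def mean_angle_to(self, direction: tuple[float, float]) -> float:
        """Mean unsigned angle (degrees) of valid vectors to a reference."""
        ref = np.asarray(direction, dtype=float)
        ref = ref / np.linalg.norm(ref)
        v = self.vectors[self.mask]
        norms = np.linalg.norm(v, axis=1)
        v = v[norms > 0]
        cos = np.clip((v @ ref) / np.linalg.norm(v, axis=1), -1.0, 1.0)
        return float(np.degrees(np.arccos(cos)).mean())


def _propagate_delta(
    w: np.ndarray, x: np.ndarray, tf_i: int, spec: PerturbationSpec
) -> np.ndarray:
    """Clipped n-hop propagation of a clamped TF shift; w is W[target, reg]."""
    if spec.mode == "KO":
        fixed = -x[:, tf_i]
    else:
        fixed = spec.oe_multiplier * x[:, tf_i].max() - x[:, tf_i]
    delta = np.zeros_like(x)
    delta[:, tf_i] = fixed
    for _ in range(spec.n_steps):
        delta = delta @ w.T
        delta[:, tf_i] = fixed
        delta = np.maximum(x + delta, 0.0) - x
    return delta


def propagate_perturbation(
    grn: GRNResults,
    adata: ad.AnnData,
    spec: PerturbationSpec,
    layer: str = "lognorm",
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Propagate a TF perturbation through the GRN.

    Returns the per-cell gene shift matrix delta (cells x GRN genes) and the
    gene tuple indexing its columns.  The perturbed TF's shift is held fixed
    at (target value - observed value); each hop multiplies the current
    shift by the coefficient matrix, after which implied expression is
    clipped at zero.
    """
    pruned = grn.prune(spec.edge_budget)
    genes = tuple(g for g in pruned.gene_universe if g in set(adata.var_names))
    if spec.tf not in genes:
        near = difflib.get_close_matches(spec.tf, genes, n=3)
        raise ValueError(f"TF {spec.tf!r} not in the GRN universe; nearest: {near}")
    w = pruned.weight_matrix(genes).to_numpy().T  # W[target, regulator]
    idx = {g: i for i, g in enumerate(genes)}
    cols = [adata.var_names.get_loc(g) for g in genes]
    x = np.asarray(adata.layers[layer])[:, cols]
    tf_i = idx[spec.tf]
    if not np.any(w[:, tf_i]):
        warnings.warn(f"TF {spec.tf!r} has no outgoing edges; shift stays local")
    return _propagate_delta(w, x, tf_i, spec), genes


class PerturbationEngine:
    """Shared machinery for systematic KO/OE simulation of many TFs.

    Precomputes the kNN neighbourhood structure, centred neighbour
    expression differences and the grid kernel once, so that simulating all
    TFs in both modes reuses the expensive pieces.

    Simulations run on k-NN-imputed expression (each cell replaced by the
    mean of its ``impute_k`` nearest embedding neighbours, following the
    simulation tool this module reimplements): both the perturbation deltas
    and the neighbour expression differences are computed on the smoothed
    matrix, which makes KO and OE fields of the same TF mirror each other
    instead of picking noise-matched neighbours.  ``impute_k=0`` disables
    imputation; the default ``None`` uses 2.5% of the cells (minimum 5).

    Parameters mirror the vector-field defaults: ``k_neighbors``
    min(200, n-1), softmax ``temperature`` 0.05, 14x14 grid, Gaussian kernel
    sigma equal to the grid spacing, mass floor 10% of the densest point.
    """

    def __init__(
        self,
        grn: GRNResults,
        adata: ad.AnnData,
        layer: str = "lognorm",
        k_neighbors: int | None = None,
        temperature: float = 0.05,
        grid_size: int = 14,
        kernel_sigma: float | None = None,
        n_steps: int = 3,
        edge_budget: int = 10_000,
        states: tuple[str, ...] | None = None,
        mass_floor: float = 0.1,
        impute_k: int | None = None,
        embedding_key: str = "X_emb",
    ) -> None:
        if states is not None:
            keep = adata.obs["state"].astype(str).isin(states).to_numpy()
            adata = adata[keep]
        self.adata = adata
        self.grn = grn.prune(edge_budget)
        self.layer = layer
        self.n_steps = n_steps
        self.edge_budget = edge_budget
        self.temperature = temperature
        self.grid_size = grid_size
        self.mass_floor = mass_floor

        self.genes = tuple(
            g for g in self.grn.gene_universe if g in set(adata.var_names)
        )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._w = self.grn.weight_matrix(self.genes).to_numpy().T  # [target, reg]
        cols = [adata.var_names.get_loc(g) for g in self.genes]
        self.X = np.asarray(adata.layers[layer])[:, cols]
        self.emb = np.asarray(adata.obsm[embedding_key], dtype=float)
        if self.emb.shape[1] != 2:
            raise ValueError("embedding must be 2-D")
        n = self.X.shape[0]
        self.impute_k = (
            max(5, round(0.025 * n)) if impute_k is None else int(impute_k)
        )
        if self.impute_k > 0:
            k_imp = min(self.impute_k, n)
            nn_imp = NearestNeighbors(n_neighbors=k_imp).fit(self.emb)
            _, imp_nbr = nn_imp.kneighbors(self.emb)
            self.X = self.X[imp_nbr].mean(axis=1)
        self.k = min(200 if k_neighbors is None else k_neighbors, n - 1)

        nn = NearestNeighbors(n_neighbors=self.k + 1).fit(self.emb)
        _, nbr = nn.kneighbors(self.emb)
        self.nbr = nbr[:, 1:]  # drop self

        d = self.X[self.nbr].astype(np.float32) - self.X[:, None, :].astype(np.float32)
        self._dc = d - d.mean(axis=2, keepdims=True)
        self._dnorm = np.linalg.norm(self._dc, axis=2)
        self._edisp = self.emb[self.nbr] - self.emb[:, None, :]  # (n, k, 2)
        self._edisp_mean = self._edisp.mean(axis=1)

        self.x_grid = np.linspace(self.emb[:, 0].min(), self.emb[:, 0].max(), grid_size)
        self.y_grid = np.linspace(self.emb[:, 1].min(), self.emb[:, 1].max(), grid_size)
        dx = self.x_grid[1] - self.x_grid[0] if grid_size > 1 else 1.0
        dy = self.y_grid[1] - self.y_grid[0] if grid_size > 1 else 1.0
        self.sigma = kernel_sigma if kernel_sigma is not None else 0.5 * (dx + dy)
        gx, gy = np.meshgrid(self.x_grid, self.y_grid, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        d2 = ((pts[:, None, :] - self.emb[None, :, :]) ** 2).sum(axis=2)
        self._kernel = np.exp(-d2 / (2 * self.sigma**2))  # (g*g, n)
        self.mass = self._kernel.sum(axis=1).reshape(grid_size, grid_size)
        self.mask = self.mass >= self.mass_floor * self.mass.max()

    # -- vector fields ------------------------------------------------------

    def cell_vectors(self, delta: np.ndarray) -> np.ndarray:
        """Density-corrected expected embedding displacement per cell."""
        dc = delta - delta.mean(axis=1, keepdims=True)
        dnorm = np.linalg.norm(dc, axis=1)
        num = np.einsum("ckg,cg->ck", self._dc, dc.astype(np.float32))
        denom = self._dnorm * dnorm[:, None].astype(np.float32)
        with np.errstate(divide="ignore", invalid="ignore"):
            sims = np.where(denom > 0, num / denom, 0.0).astype(np.float64)
        logits = sims / self.temperature
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return np.einsum("ck,ckd->cd", p, self._edisp) - self._edisp_mean

    def to_grid(self, vectors: np.ndarray) -> GridField:
        """Gaussian-kernel smoothing of per-cell vectors onto the grid."""
        g = self.grid_size
        num = self._kernel @ vectors  # (g*g, 2)
        with np.errstate(invalid="ignore"):
            v = num / self._kernel.sum(axis=1, keepdims=True)
        v = np.nan_to_num(v).reshape(g, g, 2)
        return GridField(
            x=self.x_grid, y=self.y_grid,
            vx=v[..., 0], vy=v[..., 1],
            mass=self.mass, mask=self.mask.copy(),
        )

    def propagate(self, tf: str, mode: str) -> np.ndarray:
        """Per-cell shift matrix for one perturbation on the engine's
        (imputed) expression; columns follow ``self.genes``."""
        spec = PerturbationSpec(
            tf=tf, mode=mode, n_steps=self.n_steps, edge_budget=self.edge_budget
        )
        if tf not in self._gene_index:
            near = difflib.get_close_matches(tf, self.genes, n=3)
            raise ValueError(f"TF {tf!r} not in the GRN universe; nearest: {near}")
        tf_i = self._gene_index[tf]
        if not np.any(self._w[:, tf_i]):
            warnings.warn(f"TF {tf!r} has no outgoing edges; shift stays local")
        return _propagate_delta(self._w, self.X, tf_i, spec)

    def simulate(self, tf: str, mode: str) -> GridField:
        return self.to_grid(self.cell_vectors(self.propagate(tf, mode)))

    def developmental_flow(self, k_regression: int = 10) -> GridField:
        return developmental_flow(
            self.adata.obs["pseudotime"].to_numpy(),
            self.emb,
            grid_size=self.grid_size,
            k_regression=k_regression,
            kernel_sigma=self.sigma,
            mass_floor=self.mass_floor,
        )

    def score_all(
        self,
        tfs: list[str] | None = None,
        modes: tuple[str, ...] = ("KO", "OE"),
        flow: GridField | None = None,
        magnitude_floor: float = 0.05,
    ) -> pd.DataFrame:
        """Perturbation-score sums for every TF and mode."""
        if flow is None:
            flow = self.developmental_flow()
        if tfs is None:
            tfs = sorted(set(self.grn.edges["regulator"]))
        rows = []
        for tf in tfs:
            for mode in modes:
                field = self.simulate(tf, mode)
                scores = perturbation_scores(field, flow, magnitude_floor)
                rows.append((tf, mode, scores["sum_positive"], scores["sum_negative"]))
        return pd.DataFrame(rows, columns=["tf", "mode", "sum_positive", "sum_negative"])


def simulation_vector_field(
    delta: np.ndarray,
    expr: np.ndarray,
    embedding: np.ndarray,
    k_neighbors: int | None = None,
    temperature: float = 0.05,
    grid_size: int = 14,
    kernel_sigma: float | None = None,
    mass_floor: float = 0.1,
) -> GridField:
    """Standalone simulation vector field from a precomputed shift matrix.

    ``delta`` and ``expr`` are cells x genes over the same gene set;
    ``embedding`` is cells x 2.  See :class:`PerturbationEngine` for the
    construction.
    """
    engine = _bare_engine(
        expr, embedding, k_neighbors, temperature, grid_size, kernel_sigma, mass_floor
    )
    return engine.to_grid(engine.cell_vectors(delta))


def _bare_engine(expr, embedding, k_neighbors, temperature, grid_size,
                 kernel_sigma, mass_floor) -> PerturbationEngine:
    engine = PerturbationEngine.__new__(PerturbationEngine)
    engine.X = np.asarray(expr, dtype=float)
    engine.emb = np.asarray(embedding, dtype=float)
    engine.temperature = temperature
    engine.grid_size = grid_size
    engine.mass_floor = mass_floor
    n = engine.X.shape[0]
    engine.k = min(200 if k_neighbors is None else k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=engine.k + 1).fit(engine.emb)
    _, nbr = nn.kneighbors(engine.emb)
    engine.nbr = nbr[:, 1:]
    d = engine.X[engine.nbr].astype(np.float32) - engine.X[:, None, :].astype(np.float32)
    engine._dc = d - d.mean(axis=2, keepdims=True)
    engine._dnorm = np.linalg.norm(engine._dc, axis=2)
    engine._edisp = engine.emb[engine.nbr] - engine.emb[:, None, :]
    engine._edisp_mean = engine._edisp.mean(axis=1)
    engine.x_grid = np.linspace(engine.emb[:, 0].min(), engine.emb[:, 0].max(), grid_size)
    engine.y_grid = np.linspace(engine.emb[:, 1].min(), engine.emb[:, 1].max(), grid_size)
    dx = engine.x_grid[1] - engine.x_grid[0] if grid_size > 1 else 1.0
    dy = engine.y_grid[1] - engine.y_grid[0] if grid_size > 1 else 1.0
    engine.sigma = kernel_sigma if kernel_sigma is not None else 0.5 * (dx + dy)
    gx, gy = np.meshgrid(engine.x_grid, engine.y_grid, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((pts[:, None, :] - engine.emb[None, :, :]) ** 2).sum(axis=2)
    engine._kernel = np.exp(-d2 / (2 * engine.sigma**2))
    engine.mass = engine._kernel.sum(axis=1).reshape(grid_size, grid_size)
    engine.mask = engine.mass >= mass_floor * engine.mass.max()
    return engine


def developmental_flow(
    pseudotime: np.ndarray,
    embedding: np.ndarray,
    grid_size: int = 14,
    k_regression: int = 10,
    kernel_sigma: float | None = None,
    mass_floor: float = 0.1,
) -> GridField:
    """Developmental flow: gradient of grid-smoothed pseudotime.

    Pseudotime is smoothed onto the grid by k-nearest-neighbour mean and the
    flow is its central-difference gradient in embedding units, masked where
    the Gaussian cell mass is low (same masking rule as simulation fields).

    The default grid resolution is deliberately coarse: the noise of a
    central-difference gradient of a k-NN mean scales inversely with the
    grid spacing, and at ~10^3 cells a grid much finer than ~14x14 leaves
    too few cells per node for a stable gradient direction.  The default
    k_regression keeps the smoothing neighbourhood diameter comparable to
    one grid spacing so adjacent nodes average nearly disjoint cell sets.
    """
    pt = np.asarray(pseudotime, dtype=float)
    emb = np.asarray(embedding, dtype=float)
    if not np.all(np.isfinite(pt)):
        raise ValueError("pseudotime must be finite")
    x_grid = np.linspace(emb[:, 0].min(), emb[:, 0].max(), grid_size)
    y_grid = np.linspace(emb[:, 1].min(), emb[:, 1].max(), grid_size)
    gx, gy = np.meshgrid(x_grid, y_grid, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])

    k = min(k_regression, len(pt))
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    _, nbr = nn.kneighbors(pts)
    pt_grid = pt[nbr].mean(axis=1).reshape(grid_size, grid_size)

    if grid_size > 1:
        gradx, grady = np.gradient(pt_grid, x_grid, y_grid)
    else:
        gradx = grady = np.zeros_like(pt_grid)

    dx = x_grid[1] - x_grid[0] if grid_size > 1 else 1.0
    dy = y_grid[1] - y_grid[0] if grid_size > 1 else 1.0
    sigma = kernel_sigma if kernel_sigma is not None else 0.5 * (dx + dy)
    d2 = ((pts[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2)
    mass = np.exp(-d2 / (2 * sigma**2)).sum(axis=1).reshape(grid_size, grid_size)
    mask = mass >= mass_floor * mass.max()
    return GridField(x=x_grid, y=y_grid, vx=gradx, vy=grady, mass=mass, mask=mask)


def perturbation_scores(
    sim: GridField, flow: GridField, magnitude_floor: float = 0.05
) -> dict:
    """Per-grid perturbation scores and their positive/negative sums.

    PS at each jointly valid grid point is the inner product of the
    L2-normalised simulation and flow vectors (so PS is in [-1, 1]); grid
    vectors with norm below ``magnitude_floor`` of the field's maximum valid
    norm count as zero and give PS 0.
    """
    if sim.vx.shape != flow.vx.shape:
        raise ValueError("fields must share the grid")
    mask = sim.mask & flow.mask

    def _unit(field: GridField) -> np.ndarray:
        v = field.vectors
        norm = np.linalg.norm(v, axis=-1)
        valid_norms = norm[mask]
        floor = magnitude_floor * (valid_norms.max() if valid_norms.size else 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where((norm > floor)[..., None] & (norm > 0)[..., None],
                         v / np.maximum(norm, 1e-300)[..., None], 0.0)
        return u

    ps = (_unit(sim) * _unit(flow)).sum(axis=-1)
    ps = np.where(mask, ps, 0.0)
    return {
        "ps": ps,
        "sum_positive": float(np.maximum(ps, 0.0)[mask].sum()),
        "sum_negative": float(np.minimum(ps, 0.0)[mask].sum()),
    }


def rank_tfs(
    score_table: pd.DataFrame,
    stim_neg_threshold: float = -1.0,
    stim_pos_threshold: float = 0.75,
    block_pos_threshold: float = 1.0,
) -> pd.DataFrame:
    """Classify TFs from knockout perturbation-score sums.

    Stimulators of trajectory progression have a strongly negative KO score
    with little positive KO score; blockers have a strongly positive KO
    score; TFs exceeding both bounds are context-specific.  The returned
    table is ranked by ascending negative KO score (strongest stimulators
    first).
    """
    ko = score_table[score_table["mode"] == "KO"].set_index("tf")
    all_tfs = sorted(score_table["tf"].unique())
    missing = set(all_tfs) - set(ko.index)
    if missing:
        raise ValueError(f"KO rows missing for TFs: {sorted(missing)}")
    rows = []
    for tf in all_tfs:
        spos = float(ko.loc[tf, "sum_positive"])
        sneg = float(ko.loc[tf, "sum_negative"])
        if sneg < stim_neg_threshold and spos > block_pos_threshold:
            cls = "context-specific"
        elif sneg < stim_neg_threshold and spos < stim_pos_threshold:
            cls = "stimulator"
        elif spos > block_pos_threshold:
            cls = "blocker"
        else:
            cls = "none"
        rows.append((tf, sneg, spos, cls))
    out = pd.DataFrame(
        rows, columns=["tf", "ko_sum_negative", "ko_sum_positive", "class"]
    )
    return out.sort_values(
        ["ko_sum_negative", "tf"], kind="mergesort"
    ).reset_index(drop=True)
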