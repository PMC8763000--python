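"""RNA velocity under the steady-state model, in cell and metagene space.

At transcriptional equilibrium, unspliced and spliced abundance of a gene
are proportional: ``u = gamma * s``.  The steady-state ratio ``gamma`` is
fit per gene as the slope of a zero-intercept regression of u on s over
the cells in the extreme expression quantiles (the pooled lower and upper
tails, where the equilibrium assumption is most defensible); velocity is
the residual ``v = u - gamma * s``, positive where transcription runs
ahead of splicing (expression about to rise) and negative where it lags.

Velocities are aggregated two ways: into metagene (SOM-grid) space, where
a unit's velocity is the mean velocity of its member genes — forecasting
which regions of the expression portrait are switching on or off in each
treatment group — and into a 2-D cell embedding, where each cell's
velocity vector is matched against the expression displacement toward its
embedding neighbors and the neighbor directions are averaged under an
exponential kernel of that correlation (the uniform-average baseline is
subtracted, so zero velocity yields an exactly zero field).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .som import SOMModel

logger = logging.getLogger(__name__)


@dataclass
class VelocityMatrices:
    """Spliced/unspliced layers with fitted ratios and velocities.

    ``gamma`` is NaN for genes that could not be fit (too few usable
    cells or no spliced signal); their velocity columns are zeroed and
    masked out of every aggregation via ``fitted``.
    """

    spliced: np.ndarray  # cells x genes
    unspliced: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray | None = None
    gamma: np.ndarray | None = None
    velocity: np.ndarray | None = None
    fit_quantiles: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        self.spliced = np.asarray(self.spliced, dtype=float)
        self.unspliced = np.asarray(self.unspliced, dtype=float)
        if self.spliced.shape != self.unspliced.shape:
            raise ValueError("spliced and unspliced shapes differ")
        if np.any(self.spliced < 0) or np.any(self.unspliced < 0):
            raise ValueError("spliced/unspliced must be nonnegative")
        if len(self.gene_ids) != self.spliced.shape[1]:
            raise ValueError("gene_ids length does not match matrices")
        lo, hi = self.fit_quantiles
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("fit_quantiles must satisfy 0 < lo < hi < 1")

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[1]

    @property
    def fitted(self) -> np.ndarray:
        if self.gamma is None:
            raise ValueError("gamma has not been fit")
        return np.isfinite(self.gamma)


def knn_pool(
    s: np.ndarray, u: np.ndarray, n_neighbors: int = 30, n_pcs: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth both layers by averaging over k nearest expression neighbors.

    The neighbor graph is built on principal components of log1p spliced
    counts; each cell's pooled profile is the mean over itself and its
    neighbors.  Pooling preserves exact proportionality: if ``u = g * s``
    per gene, the pooled layers satisfy the same relation.
    """
    n_cells = s.shape[0]
    k = min(n_neighbors, n_cells - 1)
    n_pcs = min(n_pcs, n_cells - 1, s.shape[1])
    pcs = PCA(n_components=n_pcs, svd_solver="randomized",
              random_state=seed).fit_transform(np.log1p(s))
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, nbr = nn.kneighbors(pcs)
    pool = np.concatenate([np.arange(n_cells)[:, None], nbr], axis=1)
    return s[pool].mean(axis=1), u[pool].mean(axis=1)


def fit_gamma(
    u: np.ndarray, s: np.ndarray, q: tuple[float, float] = (0.05, 0.95),
    min_cells: int = 10,
) -> np.ndarray:
    """Per-gene steady-state ratio from extreme-quantile regression.

    For each gene, cells in the pooled lower/upper ``q`` tails of the
    gene's expression are selected and ``gamma = sum(u*s) / sum(s^2)``
    over those cells (zero-intercept least squares).  Extremeness is
    judged on the combined max-normalized signal ``s/max(s) + u/max(u)``:
    because the count noise of the two layers is independent, selecting
    on their sum keeps the tails anchored to genuinely induced/repressed
    cells instead of to noise excursions of the regressor, which would
    attenuate the slope.  Genes with fewer than ``min_cells`` usable
    cells (nonzero in either layer) among the selected, or with no
    spliced signal there, are flagged unfit (NaN).
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if u.shape != s.shape:
        raise ValueError("u and s shapes differ")
    lo_q, hi_q = q
    smax = np.maximum(s.max(axis=0), 1e-12)
    umax = np.maximum(u.max(axis=0), 1e-12)
    z = s / smax[None, :] + u / umax[None, :]
    lo = np.quantile(z, lo_q, axis=0)
    hi = np.quantile(z, hi_q, axis=0)
    sel = (z <= lo[None, :]) | (z >= hi[None, :])
    usable = (sel & ((s > 0) | (u > 0))).sum(axis=0)
    num = (u * s * sel).sum(axis=0)
    den = (s * s * sel).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = num / den
    unfit = (usable < min_cells) | (den <= 0) | ~np.isfinite(gamma)
    gamma[unfit] = np.nan
    if unfit.any():
        logger.info("fit_gamma: %d/%d genes flagged unfit", int(unfit.sum()), len(gamma))
    return gamma


def compute_velocity(vm: VelocityMatrices) -> VelocityMatrices:
    """Set ``v = u - gamma * s`` per fitted gene (unfit columns zeroed)."""
    if vm.gamma is None:
        raise ValueError("fit gamma before computing velocity")
    fitted = vm.fitted
    v = np.zeros_like(vm.spliced)
    v[:, fitted] = vm.unspliced[:, fitted] - vm.gamma[fitted][None, :] * vm.spliced[:, fitted]
    return replace(vm, velocity=v)


def estimate_velocity(
    spliced: np.ndarray,
    unspliced: np.ndarray,
    gene_ids: np.ndarray,
    cell_ids: np.ndarray | None = None,
    q: tuple[float, float] = (0.05, 0.95),
    smooth: bool = True,
    n_neighbors: int = 30,
    seed: int = 0,
) -> VelocityMatrices:
    """Convenience pipeline: optional kNN pooling, gamma fit, velocity."""
    s = np.asarray(spliced, dtype=float)
    u = np.asarray(unspliced, dtype=float)
    if smooth:
        s, u = knn_pool(s, u, n_neighbors=n_neighbors, seed=seed)
    vm = VelocityMatrices(spliced=s, unspliced=u, gene_ids=np.asarray(gene_ids),
                          cell_ids=cell_ids, fit_quantiles=q)
    vm.gamma = fit_gamma(u, s, q=q)
    return compute_velocity(vm)


@dataclass
class MetageneVelocityField:
    """Per-unit velocity on the SOM grid, one field per cell group."""

    fields: dict[str, np.ndarray]
    grid_shape: tuple[int, int]
    cell_field: np.ndarray | None = None  # per-cell 2-vectors, if projected

    def __getitem__(self, group: str) -> np.ndarray:
        return self.fields[group]


def metagene_velocity(
    vm: VelocityMatrices,
    model: SOMModel,
    cells: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> MetageneVelocityField:
    """Aggregate gene velocities onto the SOM grid.

    A unit's velocity is the mean of its member genes' velocities,
    averaged over the selected cells (mean rather than sum, so units with
    different gene counts stay comparable); units without fitted member
    genes are 0.  With ``groups``, one field per group label is returned.
    """
    if vm.velocity is None:
        raise ValueError("compute velocity first")
    gene_pos = {g: i for i, g in enumerate(vm.gene_ids)}
    K = model.n_units
    unit_cols: list[np.ndarray] = []
    for members in model.unit_members:
        cols = [gene_pos[g] for g in members if g in gene_pos]
        cols = [c for c in cols if np.isfinite(vm.gamma[c])]
        unit_cols.append(np.array(cols, dtype=int))
    if not any(len(c) for c in unit_cols):
        raise ValueError("model genes and velocity genes are disjoint")

    idx = np.arange(vm.n_cells) if cells is None else np.asarray(list(cells), dtype=int)
    if groups is None:
        group_map = {"all": idx}
    else:
        groups = np.asarray(groups)
        group_map = {str(g): idx[groups[idx] == g] for g in pd.unique(groups[idx])}

    fields = {}
    for name, gidx in group_map.items():
        vals = np.zeros(K)
        vsub = vm.velocity[gidx]
        for uix, cols in enumerate(unit_cols):
            if len(cols):
                vals[uix] = vsub[:, cols].mean()
        fields[name] = vals.reshape(model.grid_shape)
    return MetageneVelocityField(fields=fields, grid_shape=model.grid_shape)


def embedding_field(
    vm: VelocityMatrices,
    emb: np.ndarray,
    k: int = 30,
    kernel_width: float = 0.05,
    center_genes: bool = True,
) -> np.ndarray:
    """Project velocities onto a 2-D cell embedding.

    Each cell's velocity vector is correlated (Pearson, over fitted
    genes) with the expression displacement to each of its ``k`` nearest
    embedding neighbors; the unit direction toward each neighbor is
    averaged with weights ``softmax(corr / kernel_width)`` and the
    unweighted mean direction is subtracted, so cells with zero (or
    uninformative) velocity get an exactly zero vector.

    With ``center_genes`` (default), each gene's velocity is centered
    across cells first.  The steady-state fit absorbs systematic
    unspliced excess into the per-gene ratio, shifting every cell's
    velocity for that gene by a constant; only the cell-to-cell contrast
    carries directional information, and centering removes the arbitrary
    offset before it can masquerade as coherent flow.
    """
    if vm.velocity is None:
        raise ValueError("compute velocity first")
    emb = np.asarray(emb, dtype=float)
    n = vm.n_cells
    if emb.shape != (n, 2):
        raise ValueError("embedding must be cells x 2")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")

    fitted = vm.fitted
    V = vm.velocity[:, fitted]
    if center_genes:
        V = V - V.mean(axis=0, keepdims=True)
    S = vm.spliced[:, fitted]

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, nbr = nn.kneighbors(emb)
    nbr = nbr[:, 1:]  # drop self

    out = np.zeros((n, 2))
    for i in range(n):
        js = nbr[i]
        disp = S[js] - S[i]  # k x genes
        v = V[i]
        v_c = v - v.mean()
        v_sd = np.linalg.norm(v_c)
        # numerically-zero velocity carries no direction: correlation with
        # the residue would be pure noise, so the cell's vector stays 0
        if v_sd <= 1e-10 * (1.0 + np.linalg.norm(S[i])):
            continue
        d_c = disp - disp.mean(axis=1, keepdims=True)
        d_sd = np.linalg.norm(d_c, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (d_c @ v_c) / (d_sd * v_sd)
        corr = np.nan_to_num(corr, nan=0.0)

        dvec = emb[js] - emb[i]
        dist = np.linalg.norm(dvec, axis=1)
        ok = dist > 0
        if not ok.any():
            continue
        dirs = dvec[ok] / dist[ok, None]
        w = np.exp(corr[ok] / kernel_width)
        w = w / w.sum()
        out[i] = w @ dirs - dirs.mean(axis=0)
    return out


def state_flow_scores(
    field: np.ndarray, emb: np.ndarray, labels: np.ndarray,
) -> pd.Series:
    """Net outward-flow score per state in an embedding velocity field.

    For each state, the score is the mean projection of its cells' field
    vectors onto the unit vector from the global centroid to the state
    centroid: positive scores mean the state's cells flow outward, away
    from the rest of the population (a source); near-zero or negative
    scores mark stable or receiving states.
    """
    emb = np.asarray(emb, dtype=float)
    labels = np.asarray(labels)
    center = emb.mean(axis=0)
    scores = {}
    for state in pd.unique(labels):
        idx = np.flatnonzero(labels == state)
        direction = emb[idx].mean(axis=0) - center
        norm = np.linalg.norm(direction)
        if norm == 0:
            scores[state] = 0.0
            continue
        direction /= norm
        scores[state] = float((field[idx] @ direction).mean())
    return pd.Series(scores, name="outward_flow")
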