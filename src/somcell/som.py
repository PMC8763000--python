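"""Gene-space self-organizing maps and expression portraits.

A Kohonen network is trained on *gene* profiles: each training vector is
one gene's centralized log expression across all cells, so the map places
co-expressed genes on nearby units of a rectangular grid (60x60 by
default, i.e. K = 3,600 metagenes).  Each unit's codebook vector is a
prototype expression profile of length ``n_cells``; evaluating all K
prototypes at a single cell's coordinate yields that cell's grid-shaped
"portrait" of over- and under-expressed metagenes.

Training is the classic online scheme: genes are presented one at a time
in shuffled order, the best-matching unit (BMU) is the codebook row with
the smallest Euclidean distance, and the units within the current
neighborhood radius of the BMU are pulled toward the gene profile with a
Gaussian weight profile (width = radius/2, truncated at the radius).
Neighborhood radius and learning rate decay exponentially between their
initial and final values over the epochs.  Everything is deterministic
under the configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numba
import numpy as np
import pandas as pd

from .prep import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SOMConfig:
    """Self-organizing-map geometry and training schedule.

    The default 60x60 grid gives K = 3,600 metagene units.  ``epochs`` is
    the number of full passes over the gene set; radius and learning rate
    decay exponentially from their initial to final values across epochs.
    ``initial_radius`` defaults to half the larger grid dimension.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    epochs: int = 20
    initial_radius: float | None = None
    final_radius: float = 1.0
    initial_lr: float = 0.1
    final_lr: float = 0.01
    init_mode: str = "seeded-random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError("grid dimensions must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_radius is None:
            self.initial_radius = max(self.grid_rows, self.grid_cols) / 2.0
        if self.final_radius <= 0 or self.initial_radius < self.final_radius:
            raise ValueError("radii must be positive with initial >= final")
        if not (0 < self.final_lr <= self.initial_lr < 1):
            raise ValueError("learning rates must satisfy 0 < final <= initial < 1")
        if self.init_mode not in ("seeded-random", "pca-plane"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass
class SOMModel:
    """A trained gene-space SOM.

    ``codebook`` is ``(K, n_cells)``; row ``u`` is unit ``u``'s prototype
    profile, with units enumerated row-major on the grid.  ``bmu[g]`` is
    the best-matching unit of gene ``g`` at convergence and
    ``unit_members[u]`` lists the gene ids assigned to unit ``u`` (a
    partition of the gene set).  ``quantization_error_trace`` holds the
    mean squared gene-to-BMU distance per epoch, measured at presentation
    time; ``qe_initial``/``qe_final`` are exact values computed before and
    after training.
    """

    config: SOMConfig
    codebook: np.ndarray
    bmu: np.ndarray
    unit_members: list[list[str]]
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    quantization_error_trace: np.ndarray
    qe_initial: float
    qe_final: float
    cell_groups: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.config.grid_rows, self.config.grid_cols)

    @property
    def n_units(self) -> int:
        return self.codebook.shape[0]

    @property
    def n_cells(self) -> int:
        return self.codebook.shape[1]

    def unit_coords(self, unit: int | np.ndarray) -> np.ndarray:
        """(row, col) grid coordinates of unit index/indices."""
        return np.stack(np.unravel_index(unit, self.grid_shape), axis=-1)

    def save(self, out_dir: str | Path) -> None:
        """Persist codebook, BMU table and config echo as plain text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.codebook, columns=list(self.cell_ids)).to_csv(
            out / "codebook.tsv", sep="\t", index=False)
        coords = self.unit_coords(self.bmu)
        pd.DataFrame({"gene_id": self.gene_ids, "row": coords[:, 0],
                      "col": coords[:, 1]}).to_csv(
            out / "bmu.tsv", sep="\t", index=False)


@dataclass
class Portrait:
    """A grid-shaped view of metagene values for one cell or cell set."""

    values: np.ndarray
    subject: str
    kind: str = "single-cell"  # single-cell | mean | difference

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("portrait values must be 2-D")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape


@numba.njit(cache=True, fastmath=True)
def _run_epoch(X, X32, W, W32, w_norm2, x_norm2, order, rows, cols, lr, radius):
    """One online epoch: sequential BMU search + neighborhood updates.

    BMU scoring runs on the float32 shadow codebook (bandwidth-bound);
    the float64 master codebook accumulates the updates.  The Gaussian
    neighborhood (width radius/2) is truncated at grid distance
    ``radius``.  Returns the summed squared BMU distance at presentation
    time.
    """
    K, C = W.shape
    inv2s2 = 1.0 / (2.0 * (radius / 2.0) ** 2)
    r_int = int(np.floor(radius))
    r2 = radius * radius
    qe = 0.0
    for t in range(order.shape[0]):
        g = order[t]
        xg32 = X32[g]
        best = 0
        best_d = np.inf
        for k in range(K):
            sc = 0.0
            wk32 = W32[k]
            for j in range(C):
                sc += wk32[j] * xg32[j]
            d = w_norm2[k] - 2.0 * sc
            if d < best_d:
                best_d = d
                best = k
        qe += max(best_d + x_norm2[g], 0.0)
        br = best // cols
        bc = best % cols
        xg = X[g]
        for rr in range(max(br - r_int, 0), min(br + r_int, rows - 1) + 1):
            for cc in range(max(bc - r_int, 0), min(bc + r_int, cols - 1) + 1):
                d2 = (rr - br) ** 2 + (cc - bc) ** 2
                if d2 > r2:
                    continue
                k = rr * cols + cc
                h = lr * np.exp(-d2 * inv2s2)
                wk = W[k]
                nrm = 0.0
                for j in range(C):
                    wk[j] += h * (xg[j] - wk[j])
                    nrm += wk[j] * wk[j]
                w_norm2[k] = nrm
                for j in range(C):
                    W32[k, j] = wk[j]
    return qe


def _init_codebook(X: np.ndarray, cfg: SOMConfig, rng: np.random.Generator) -> np.ndarray:
    K = cfg.n_units
    if cfg.init_mode == "seeded-random":
        # each prototype starts as the mean of several random gene profiles:
        # inside the (centered) data subspace, so codebook rows stay exact
        # linear combinations of gene profiles throughout training, yet far
        # enough from any single gene that training reduces quantization error
        m = min(32, X.shape[0])
        W = np.zeros((K, X.shape[1]))
        for _ in range(m):
            W += X[rng.integers(0, X.shape[0], size=K)]
        W /= m
        return W
    # pca-plane: span the grid with the two leading principal axes
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scale = s[:2] / np.sqrt(max(X.shape[0] - 1, 1))
    a = np.linspace(-2, 2, cfg.grid_rows) * scale[0]
    b = np.linspace(-2, 2, cfg.grid_cols) * (scale[1] if len(s) > 1 else 0.0)
    plane = (a[:, None, None] * vt[0][None, None, :]
             + b[None, :, None] * (vt[1] if len(s) > 1 else np.zeros_like(vt[0]))[None, None, :])
    return (mean + plane).reshape(K, X.shape[1])


def _exact_bmu(X: np.ndarray, W: np.ndarray, chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Exact BMU index and squared distance per gene (ties -> lowest unit)."""
    w_norm2 = np.einsum("ij,ij->i", W, W)
    bmu = np.empty(X.shape[0], dtype=np.int64)
    d2 = np.empty(X.shape[0])
    for start in range(0, X.shape[0], chunk):
        xs = X[start:start + chunk]
        scores = xs @ W.T
        dist = w_norm2[None, :] - 2.0 * scores
        idx = np.argmin(dist, axis=1)
        bmu[start:start + chunk] = idx
        x_norm2 = np.einsum("ij,ij->i", xs, xs)
        d2[start:start + chunk] = dist[np.arange(len(xs)), idx] + x_norm2
    return bmu, np.maximum(d2, 0.0)


def train_som(m: ExpressionMatrix, cfg: SOMConfig | None = None) -> SOMModel:
    """Train a gene-space SOM on a centralized log-expression matrix.

    Training vectors are gene profiles (length ``n_cells``); the returned
    model's ``codebook`` has one prototype profile per grid unit and the
    gene->unit assignment (``bmu``, ``unit_members``) is recomputed
    exactly after the last epoch.
    """
    cfg = cfg if cfg is not None else SOMConfig()
    if not (m.is_log and m.is_centralized):
        raise ValueError("train_som requires a log-transformed, centralized matrix")
    if m.n_cells < 2:
        raise ValueError("train_som requires at least 2 cells")

    X = np.ascontiguousarray(m.values.T, dtype=np.float64)  # genes x cells
    X32 = X.astype(np.float32)
    n_genes = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    W = _init_codebook(X, cfg, rng)
    W32 = W.astype(np.float32)

    w_norm2 = np.einsum("ij,ij->i", W, W)
    x_norm2 = np.einsum("ij,ij->i", X, X)

    _, d2_init = _exact_bmu(X, W)
    qe_initial = float(d2_init.mean())

    T = cfg.epochs
    trace = np.empty(T)
    for epoch in range(T):
        frac = epoch / (T - 1) if T > 1 else 1.0
        radius = cfg.initial_radius * (cfg.final_radius / cfg.initial_radius) ** frac
        lr = cfg.initial_lr * (cfg.final_lr / cfg.initial_lr) ** frac
        order = rng.permutation(n_genes)
        qe_acc = _run_epoch(X, X32, W, W32, w_norm2, x_norm2, order,
                            cfg.grid_rows, cfg.grid_cols, lr, radius)
        trace[epoch] = qe_acc / n_genes

    bmu, d2_final = _exact_bmu(X, W)
    qe_final = float(d2_final.mean())
    unit_members: list[list[str]] = [[] for _ in range(cfg.n_units)]
    for g, b in enumerate(bmu):
        unit_members[b].append(m.gene_ids[g])

    logger.info("SOM trained: %dx%d grid, %d genes, QE %.4f -> %.4f",
                cfg.grid_rows, cfg.grid_cols, n_genes, qe_initial, qe_final)
    return SOMModel(
        config=cfg,
        codebook=W,
        bmu=bmu,
        unit_members=unit_members,
        gene_ids=np.asarray(m.gene_ids, dtype=object),
        cell_ids=np.asarray(m.cell_ids, dtype=object),
        quantization_error_trace=trace,
        qe_initial=qe_initial,
        qe_final=qe_final,
        cell_groups=None if m.cell_groups is None else np.asarray(m.cell_groups, dtype=object),
    )


def cell_portrait(model: SOMModel, cell_index: int) -> Portrait:
    """The portrait of one cell: every unit's codebook value at that cell."""
    if not (0 <= cell_index < model.n_cells):
        raise IndexError(f"cell index {cell_index} out of range")
    values = model.codebook[:, cell_index].reshape(model.grid_shape)
    return Portrait(values=values, subject=str(model.cell_ids[cell_index]),
                    kind="single-cell")


def mean_portrait(model: SOMModel, cell_indices, subject: str | None = None) -> Portrait:
    """Elementwise mean of the member cells' portraits."""
    idx = np.asarray(list(cell_indices), dtype=int)
    if idx.size == 0:
        raise ValueError("mean_portrait requires a nonempty cell set")
    values = model.codebook[:, idx].mean(axis=1).reshape(model.grid_shape)
    if subject is None:
        subject = f"mean({idx.size} cells)"
    return Portrait(values=values, subject=subject, kind="mean")


def group_portraits(model: SOMModel, groups: np.ndarray | None = None) -> dict[str, Portrait]:
    """Mean portrait per treatment group (or any label vector over cells)."""
    labels = groups if groups is not None else model.cell_groups
    if labels is None:
        raise ValueError("no group labels available")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != model.n_cells:
        raise ValueError("group labels do not match model cells")
    return {
        str(g): mean_portrait(model, np.flatnonzero(labels == g), subject=str(g))
        for g in pd.unique(labels)
    }
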