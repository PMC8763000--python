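"""Expression input, log/centralization transforms and cell downsampling.

The preprocessing contract of the portrait pipeline is deliberately small:
read a count matrix (10x-style MatrixMarket triplets or a dense TSV) with a
cell-metadata table, apply generic count QC, log-transform and centralize
gene-wise, equalize treatment-group sizes by random subsampling (2,000
cells per condition by default, so each condition carries equal weight
downstream), and finally thin the data by cluster-stratified sampling:
cells are grouped into communities on a kNN graph (27 strata by default)
and a fixed fraction (20% by default) is drawn per stratum and treatment
group, preserving the intrinsic heterogeneity at a fraction of the size.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Cells x genes expression with identity, group labels and scale flags.

    ``values`` holds raw counts until :func:`log_centralize` sets
    ``is_log``/``is_centralized``; centralization means every gene has zero
    mean across cells (within 1e-8).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_groups: np.ndarray | None = None
    is_log: bool = False
    is_centralized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match values")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match values")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if self.cell_groups is not None:
            self.cell_groups = np.asarray(self.cell_groups, dtype=object)
            if len(self.cell_groups) != n_cells:
                raise ValueError("cell_groups length does not match values")
        if self.is_centralized:
            col_means = self.values.mean(axis=0)
            if np.any(np.abs(col_means) > 1e-8):
                raise ValueError("matrix flagged centralized but gene means != 0")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        """Return a copy restricted to ``index`` (positions, order kept)."""
        index = np.asarray(index)
        return ExpressionMatrix(
            values=self.values[index],
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[index],
            cell_groups=None if self.cell_groups is None else self.cell_groups[index],
            is_log=self.is_log,
            is_centralized=False,  # subsetting cells breaks exact zero means
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            values=self.values[:, index],
            gene_ids=self.gene_ids[index],
            cell_ids=self.cell_ids.copy(),
            cell_groups=None if self.cell_groups is None else self.cell_groups.copy(),
            is_log=self.is_log,
            is_centralized=self.is_centralized,
        )


@dataclass
class PrepConfig:
    """Preprocessing parameters.

    ``target_cells_per_group`` equalizes condition weights (default 2,000
    cells per condition); ``n_strata`` and ``sample_fraction`` control the
    cluster-stratified thinning (27 strata, 20% per stratum and group by
    default).  ``n_strata`` is a goal for the community-detection
    resolution search, not a hard contract — any count within ±20% is
    accepted.
    """

    target_cells_per_group: int = 2000
    n_strata: int = 27
    sample_fraction: float = 0.20
    stratification_resolution: float | None = None
    n_pcs: int = 30
    n_neighbors: int = 15
    min_cells_gene: int = 3
    min_genes_cell: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_cells_per_group < 1:
            raise ValueError("target_cells_per_group must be >= 1")
        if not (0.0 < self.sample_fraction <= 1.0):
            raise ValueError("sample_fraction must lie in (0, 1]")
        if self.n_strata < 1:
            raise ValueError("n_strata must be >= 1")


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def _read_mtx_dir(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    matrix_path = path / "matrix.mtx"
    features_path = path / "features.tsv"
    barcodes_path = path / "barcodes.tsv"
    for p in (matrix_path, features_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(f"missing expected input file: {p}")
    mat = spio.mmread(str(matrix_path))
    values = np.asarray(sparse.csr_matrix(mat).todense(), dtype=float).T  # -> cells x genes
    features = pd.read_csv(features_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    gene_ids = features.iloc[:, 0].to_numpy(dtype=object)
    cell_ids = barcodes.iloc[:, 0].to_numpy(dtype=object)
    return values, gene_ids, cell_ids


def _read_dense_tsv(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # dense convention: genes as rows (index), cells as columns (header)
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float).T
    return values, df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object)


def read_matrix(
    source: str | os.PathLike,
    metadata: str | os.PathLike,
    group_column: str = "group",
) -> ExpressionMatrix:
    """Read counts (MTX triplet directory or dense TSV) plus cell metadata.

    Cells are aligned to the metadata table by barcode; barcodes absent
    from the metadata are dropped with a logged count.  Raises if the
    barcode overlap is empty or the group column is missing.
    """
    source = Path(source)
    if source.is_dir():
        values, gene_ids, cell_ids = _read_mtx_dir(source)
    elif source.exists():
        values, gene_ids, cell_ids = _read_dense_tsv(source)
    else:
        raise FileNotFoundError(f"no such expression input: {source}")

    meta = pd.read_csv(metadata, sep="\t")
    barcode_col = "barcode" if "barcode" in meta.columns else meta.columns[0]
    if group_column not in meta.columns:
        raise ValueError(
            f"metadata {metadata} has no {group_column!r} column "
            f"(columns: {list(meta.columns)})"
        )
    meta = meta.set_index(barcode_col)
    known = np.array([c in meta.index for c in cell_ids])
    n_dropped = int((~known).sum())
    if known.sum() == 0:
        raise ValueError("no overlap between matrix barcodes and metadata")
    if n_dropped:
        logger.warning("dropping %d cells with barcodes absent from metadata", n_dropped)
    cell_ids = cell_ids[known]
    values = values[known]
    groups = meta.loc[cell_ids, group_column].to_numpy(dtype=object)
    return ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids,
                            cell_groups=groups)


def write_matrix(m: ExpressionMatrix, out_dir: str | os.PathLike) -> None:
    """Write a matrix as an MTX triplet directory plus a kept-cell manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "matrix.mtx"), sparse.csr_matrix(m.values.T))
    pd.DataFrame({"gene_id": m.gene_ids, "gene_name": m.gene_ids}).to_csv(
        out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(out / "barcodes.tsv", header=False, index=False)
    manifest = pd.DataFrame({"barcode": m.cell_ids})
    if m.cell_groups is not None:
        manifest["group"] = m.cell_groups
    manifest.to_csv(out / "cells.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def qc_filter(m: ExpressionMatrix, cfg: PrepConfig) -> ExpressionMatrix:
    """Drop rarely detected genes and shallow cells, preserving order.

    Genes detected (count > 0) in fewer than ``min_cells_gene`` cells and
    cells with fewer than ``min_genes_cell`` detected genes are removed.
    Gene filtering is applied first, then cell filtering on the reduced
    gene set.
    """
    detected = m.values > 0
    gene_keep = detected.sum(axis=0) >= cfg.min_cells_gene
    if not gene_keep.any():
        raise ValueError("qc_filter would remove all genes")
    detected = detected[:, gene_keep]
    cell_keep = detected.sum(axis=1) >= cfg.min_genes_cell
    if not cell_keep.any():
        raise ValueError("qc_filter would remove all cells")
    out = m.subset_genes(np.flatnonzero(gene_keep)).subset_cells(np.flatnonzero(cell_keep))
    logger.info("qc_filter kept %d/%d genes and %d/%d cells",
                out.n_genes, m.n_genes, out.n_cells, m.n_cells)
    return out


def centralize(m: ExpressionMatrix) -> ExpressionMatrix:
    """(Re-)subtract each gene's mean across cells.

    Useful after subsetting cells, which invalidates exact zero gene
    means.  Idempotent.
    """
    centered = m.values - m.values.mean(axis=0, keepdims=True)
    return ExpressionMatrix(
        values=centered,
        gene_ids=m.gene_ids.copy(),
        cell_ids=m.cell_ids.copy(),
        cell_groups=None if m.cell_groups is None else m.cell_groups.copy(),
        is_log=m.is_log,
        is_centralized=True,
    )


def log_centralize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply ``log(1 + x)`` and subtract each gene's mean across cells."""
    if m.is_log or m.is_centralized:
        raise ValueError("matrix is already log-transformed/centralized")
    if np.any(m.values < 0):
        raise ValueError("negative values cannot be log-transformed")
    logged = ExpressionMatrix(
        values=np.log1p(m.values),
        gene_ids=m.gene_ids.copy(),
        cell_ids=m.cell_ids.copy(),
        cell_groups=None if m.cell_groups is None else m.cell_groups.copy(),
        is_log=True,
    )
    return centralize(logged)


def balance_groups(m: ExpressionMatrix, cfg: PrepConfig) -> ExpressionMatrix:
    """Downsample each treatment group to ``target_cells_per_group`` cells.

    Sampling is without replacement and seeded; groups at or below the
    target are kept whole (with a warning).  Cell order is the original
    order restricted to the kept cells.
    """
    if m.cell_groups is None:
        raise ValueError("balance_groups requires cell group labels")
    rng = np.random.default_rng(cfg.seed)
    keep = np.zeros(m.n_cells, dtype=bool)
    for grp in pd.unique(m.cell_groups):
        idx = np.flatnonzero(m.cell_groups == grp)
        if len(idx) <= cfg.target_cells_per_group:
            if len(idx) < cfg.target_cells_per_group:
                logger.warning("group %s has %d cells (< target %d); kept whole",
                               grp, len(idx), cfg.target_cells_per_group)
            keep[idx] = True
        else:
            chosen = rng.choice(idx, size=cfg.target_cells_per_group, replace=False)
            keep[chosen] = True
    return m.subset_cells(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# stratified downsampling
# ---------------------------------------------------------------------------

def _community_labels(m: ExpressionMatrix, cfg: PrepConfig) -> np.ndarray:
    """kNN-graph community detection tuned toward ``cfg.n_strata`` strata."""
    n_pcs = min(cfg.n_pcs, m.n_cells - 1, m.n_genes)
    pcs = PCA(n_components=n_pcs, svd_solver="randomized",
              random_state=cfg.seed).fit_transform(m.values)
    k = min(cfg.n_neighbors, m.n_cells - 1)
    adj = kneighbors_graph(pcs, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = ig.Graph(n=m.n_cells, edges=edges)

    def detect(res: float) -> np.ndarray:
        part = leidenalg.find_partition(
            graph, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res, seed=cfg.seed, n_iterations=2)
        return np.asarray(part.membership)

    if cfg.stratification_resolution is not None:
        return detect(cfg.stratification_resolution)

    target = cfg.n_strata
    tol = max(1, int(round(0.2 * target)))
    lo, hi = 1e-3, 4.0
    labels_hi = detect(hi)
    for _ in range(6):  # make sure the bracket contains the target
        if labels_hi.max() + 1 >= target or hi > 500:
            break
        hi *= 4
        labels_hi = detect(hi)
    best_labels, best_gap = labels_hi, abs(labels_hi.max() + 1 - target)
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        labels = detect(mid)
        n = labels.max() + 1
        gap = abs(n - target)
        if gap < best_gap:
            best_labels, best_gap = labels, gap
        if gap <= tol:
            return labels
        if n < target:
            lo = mid
        else:
            hi = mid
    logger.warning("resolution search reached %d strata (target %d)",
                   best_labels.max() + 1, target)
    return best_labels


def _stratified_keep(
    strata: np.ndarray, groups: np.ndarray | None, fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Kept positions: round-half-up of fraction*size, floor 1, per stratum x group."""
    keys = strata.astype(str) if groups is None else np.char.add(
        np.char.add(strata.astype(str), "|"), groups.astype(str))
    keep: list[np.ndarray] = []
    for key in pd.unique(keys):
        idx = np.flatnonzero(keys == key)
        n_keep = max(1, int(np.floor(fraction * len(idx) + 0.5)))
        n_keep = min(n_keep, len(idx))
        keep.append(rng.choice(idx, size=n_keep, replace=False))
    return np.sort(np.concatenate(keep))


def stratified_downsample(
    m: ExpressionMatrix, cfg: PrepConfig, strata: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Thin the matrix by sampling a fixed fraction per stratum and group.

    Strata default to communities of a kNN graph built on the top
    principal components, with the resolution tuned toward
    ``cfg.n_strata``; a precomputed stratum label per cell can be supplied
    instead.  Within each stratum x treatment-group block,
    ``round(sample_fraction * size)`` cells (minimum 1, round half up) are
    drawn without replacement.
    """
    if cfg.sample_fraction == 1.0:
        return m.subset_cells(np.arange(m.n_cells))
    if strata is None:
        if not m.is_log:
            logger.warning("stratifying a non-log matrix; consider log_centralize first")
        strata = _community_labels(m, cfg)
    else:
        strata = np.asarray(strata)
        if len(strata) != m.n_cells:
            raise ValueError("strata length does not match cell count")
    n_strata = len(np.unique(strata))
    if n_strata == 1:
        logger.warning("only one stratum found; sampling globally")
    rng = np.random.default_rng(cfg.seed)
    keep = _stratified_keep(strata, m.cell_groups, cfg.sample_fraction, rng)
    logger.info("stratified sampling kept %d/%d cells across %d strata",
                len(keep), m.n_cells, n_strata)
    return m.subset_cells(keep)
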