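"""Synthetic single-cell datasets with planted co-expression programs.

The generator emulates the statistical structure of a drug-resistance
time-course experiment: four treatment groups of unequal size (sensitive
cells plus three resistance conditions), a handful of latent transcriptional
programs whose prevalence shifts across groups, negative-binomial UMI
counts, and paired spliced/unspliced layers that obey per-gene steady-state
ratios except in designated "source" states where unspliced transcripts run
ahead of splicing.  Every downstream stage of the pipeline (portraiture,
spot segmentation, state clustering, RNA velocity) is testable against the
planted ground truth it returns.

All randomness flows from a single integer seed; independent substreams for
gene-level, cell-level and count-level draws are derived from fixed offsets
so that adding draws to one stage never perturbs another.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from ._gmt import write_gmt

logger = logging.getLogger(__name__)

#: Treatment-group names: drug-sensitive (S), vemurafenib-resistant (RV),
#: and double-resistant to vemurafenib plus cobimetinib (RVC) or
#: trametinib (RVT).
DEFAULT_GROUP_NAMES = ("S", "RV", "RVC", "RVT")

#: Group sizes proportional to a realistic experiment (sensitive and
#: single-drug-resistant pools smaller than the double-resistant pools),
#: scaled to 1,800 cells total.
DEFAULT_GROUP_SIZES = (352, 134, 618, 696)

#: Per-group mixing proportions over the 7 latent programs.  Programs are
#: ordered along the resistance trajectory: the sensitive group is dominated
#: by program 0, intermediate resistance states activate programs 2-4, and
#: the double-resistant groups populate the late programs 4-6.  Rows sum
#: to 1.
DEFAULT_MIXING = (
    (0.70, 0.20, 0.05, 0.05, 0.00, 0.00, 0.00),  # S
    (0.10, 0.30, 0.40, 0.15, 0.05, 0.00, 0.00),  # RV
    (0.00, 0.05, 0.15, 0.40, 0.30, 0.10, 0.00),  # RVC
    (0.00, 0.00, 0.05, 0.15, 0.25, 0.30, 0.25),  # RVT
)


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generator.

    Parameters
    ----------
    n_groups
        Number of treatment groups.
    group_sizes
        Cells per group; unequal by default.
    group_names
        Label per group.
    n_programs
        Number of latent co-expression programs (transcriptional states).
    genes_per_program
        Inclusive ``(low, high)`` bounds for per-program gene-set size.
    n_background_genes
        Genes belonging to no program (baseline expression only).
    program_mixing
        ``n_groups x n_programs`` proportions; row ``g`` is the probability
        of each program for a cell of group ``g``.  Rows must sum to 1.
    effect_size
        Natural-log fold change of a program's genes in cells of that
        program.
    noise_sd
        Standard deviation of the cell-by-gene Gaussian noise added on the
        log-mean scale (biological variability on top of count noise).
    nb_dispersion
        Negative-binomial size parameter theta shared by all genes
        (variance ``mu + mu^2/theta``).
    base_log_mean_sd
        SD of the per-gene baseline log mean (baselines are centred at 0,
        i.e. around one count per cell).
    steady_state_ratio_range
        ``(low, high)`` of the per-gene steady-state ratio gamma relating
        unspliced to spliced abundance (``u ~ gamma * s`` at equilibrium).
    velocity_source_states
        Program indices whose cells carry an unspliced excess on their own
        program genes, marking them as transcriptional sources.
    source_inflation
        Multiplicative factor applied to the unspliced mean of source-state
        program genes, before count sampling.
    program_overlap
        If > 0, each program additionally borrows this fraction of genes
        from the next program (off by default so truth-tracking stays
        exact).
    seed
        Master seed; the dataset is bitwise-reproducible from it.
    """

    n_groups: int = 4
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    group_names: tuple[str, ...] = DEFAULT_GROUP_NAMES
    n_programs: int = 7
    genes_per_program: tuple[int, int] = (150, 700)
    n_background_genes: int = 500
    program_mixing: tuple[tuple[float, ...], ...] = DEFAULT_MIXING
    effect_size: float = 2.0
    noise_sd: float = 0.25
    nb_dispersion: float = 10.0
    base_log_mean_sd: float = 0.7
    steady_state_ratio_range: tuple[float, float] = (0.5, 3.0)
    velocity_source_states: tuple[int, ...] = (3, 4)
    source_inflation: float = 2.0
    program_overlap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        mixing = np.asarray(self.program_mixing, dtype=float)
        if mixing.shape != (self.n_groups, self.n_programs):
            raise ValueError(
                f"program_mixing shape {mixing.shape} does not match "
                f"(n_groups={self.n_groups}, n_programs={self.n_programs})"
            )
        if np.any(mixing < 0) or np.any(mixing > 1):
            raise ValueError("program_mixing entries must lie in [0, 1]")
        rowsums = mixing.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError(f"program_mixing rows must sum to 1, got {rowsums}")
        if len(self.group_sizes) != self.n_groups:
            raise ValueError("group_sizes length must equal n_groups")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group_sizes must all be >= 1")
        if len(self.group_names) != self.n_groups:
            raise ValueError("group_names length must equal n_groups")
        lo, hi = self.genes_per_program
        if lo <= 0 or hi < lo:
            raise ValueError("genes_per_program bounds must be positive and ordered")
        glo, ghi = self.steady_state_ratio_range
        if glo <= 0 or ghi < glo:
            raise ValueError("steady_state_ratio_range must be positive and ordered")
        if any(p < 0 or p >= self.n_programs for p in self.velocity_source_states):
            raise ValueError("velocity_source_states must index programs")

    @property
    def mixing_matrix(self) -> np.ndarray:
        return np.asarray(self.program_mixing, dtype=float)


@dataclass
class SyntheticDataset:
    """A generated dataset together with its planted ground truth.

    ``counts = spliced + unspliced`` is the total UMI matrix fed to the
    expression pipeline; the two layers separately drive RNA velocity.
    ``true_gene_program`` is -1 for background genes.
    """

    counts: np.ndarray  # cells x genes, nonnegative integers
    spliced: np.ndarray
    unspliced: np.ndarray
    cell_groups: np.ndarray  # group label per cell
    true_program: np.ndarray  # program index per cell
    true_gene_program: np.ndarray  # program index per gene, -1 = background
    true_gamma: np.ndarray  # per-gene steady-state ratio, > 0
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    config: SimConfig = field(repr=False)

    def __post_init__(self) -> None:
        n_cells, n_genes = self.counts.shape
        for name in ("spliced", "unspliced"):
            if getattr(self, name).shape != (n_cells, n_genes):
                raise ValueError(f"{name} shape differs from counts")
        if len(self.cell_groups) != n_cells or len(self.true_program) != n_cells:
            raise ValueError("cell label lengths do not match cell count")
        if len(self.true_gene_program) != n_genes or len(self.true_gamma) != n_genes:
            raise ValueError("gene label lengths do not match gene count")
        if np.any(self.true_gamma <= 0):
            raise ValueError("true_gamma must be positive for all genes")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def program_gene_sets(self) -> dict[str, list[str]]:
        """Planted program gene sets as ``{name: gene id list}``."""
        out: dict[str, list[str]] = {}
        for p in range(self.config.n_programs):
            members = self.gene_ids[self.true_gene_program == p]
            out[f"program_{p}"] = list(members)
        return out

    def to_expression_matrix(self):
        """Package the total counts as a :class:`somcell.prep.ExpressionMatrix`."""
        from .prep import ExpressionMatrix

        return ExpressionMatrix(
            values=self.counts.astype(float),
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids.copy(),
            cell_groups=self.cell_groups.copy(),
        )


def _substream(seed: int, offset: int) -> np.random.Generator:
    # fixed offsets keep the per-stage streams independent of one another
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(offset)]))


def simulate(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate a :class:`SyntheticDataset` from ``config``.

    Each cell draws one latent program from its group's mixing row; the
    program's genes are up-shifted by ``effect_size`` on the log scale in
    that cell.  Spliced counts are negative binomial around
    ``exp(log-mean)``; unspliced counts follow ``gamma * spliced-mean``,
    inflated by ``source_inflation`` for program genes of cells in
    ``velocity_source_states``.
    """
    cfg = config if config is not None else SimConfig()

    rng_genes = _substream(cfg.seed, 0)
    rng_cells = _substream(cfg.seed, 1)
    rng_counts = _substream(cfg.seed, 2)

    # --- gene architecture -------------------------------------------------
    lo, hi = cfg.genes_per_program
    program_sizes = rng_genes.integers(lo, hi + 1, size=cfg.n_programs)
    n_genes = int(program_sizes.sum()) + cfg.n_background_genes
    gene_program = np.full(n_genes, -1, dtype=int)
    start = 0
    bounds = []
    for p, size in enumerate(program_sizes):
        gene_program[start : start + size] = p
        bounds.append((start, start + size))
        start += size

    base_log_mean = rng_genes.normal(0.0, cfg.base_log_mean_sd, size=n_genes)
    glo, ghi = cfg.steady_state_ratio_range
    gamma = rng_genes.uniform(glo, ghi, size=n_genes)

    # --- cell states --------------------------------------------------------
    mixing = cfg.mixing_matrix
    groups = np.repeat(np.asarray(cfg.group_names, dtype=object), cfg.group_sizes)
    programs = np.concatenate(
        [
            rng_cells.choice(cfg.n_programs, size=size, p=mixing[g])
            for g, size in enumerate(cfg.group_sizes)
        ]
    )
    n_cells = len(programs)

    # --- log-mean surface ----------------------------------------------------
    log_mean = np.tile(base_log_mean, (n_cells, 1))
    # program membership indicator per cell x gene, applied program-wise to
    # avoid materialising a dense indicator
    for p, (a, b) in enumerate(bounds):
        in_p = programs == p
        log_mean[np.ix_(in_p, np.arange(a, b))] += cfg.effect_size
        if cfg.program_overlap > 0:
            # borrow a leading slice of the next program's genes
            q = (p + 1) % cfg.n_programs
            qa, qb = bounds[q]
            n_borrow = int(cfg.program_overlap * (qb - qa))
            if n_borrow:
                log_mean[np.ix_(in_p, np.arange(qa, qa + n_borrow))] += cfg.effect_size
    if cfg.noise_sd > 0:
        log_mean += rng_counts.normal(0.0, cfg.noise_sd, size=log_mean.shape)

    mu_s = np.exp(log_mean)
    mu_u = mu_s * gamma[None, :]
    for p in cfg.velocity_source_states:
        a, b = bounds[p]
        in_p = programs == p
        mu_u[np.ix_(in_p, np.arange(a, b))] *= cfg.source_inflation

    theta = cfg.nb_dispersion
    spliced = rng_counts.negative_binomial(theta, theta / (theta + mu_s))
    unspliced = rng_counts.negative_binomial(theta, theta / (theta + mu_u))
    counts = spliced + unspliced

    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    cell_ids = np.array([f"CELL{i:05d}" for i in range(n_cells)], dtype=object)

    return SyntheticDataset(
        counts=counts,
        spliced=spliced,
        unspliced=unspliced,
        cell_groups=groups,
        true_program=programs,
        true_gene_program=gene_program,
        true_gamma=gamma,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        config=cfg,
    )


def _write_mtx(path: Path, matrix: np.ndarray) -> None:
    # genes x cells orientation, 10x-style; integer MatrixMarket triplets
    spio.mmwrite(str(path), sparse.csr_matrix(matrix.T.astype(np.int64)))


def write_dataset(ds: SyntheticDataset, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write ``ds`` to ``out_dir`` in 10x-style plain-text formats.

    Emits ``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv`` (total
    counts, genes as rows), the ``spliced.mtx`` / ``unspliced.mtx`` layers,
    a ``cells.tsv`` metadata table with the treatment group and true
    program, and ``programs.gmt`` with the planted gene sets.  The files
    round-trip losslessly through :func:`somcell.prep.read_matrix`.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": out / "matrix.mtx",
            "features": out / "features.tsv",
            "barcodes": out / "barcodes.tsv",
            "spliced": out / "spliced.mtx",
            "unspliced": out / "unspliced.mtx",
            "cells": out / "cells.tsv",
            "gmt": out / "programs.gmt",
        }
        _write_mtx(paths["matrix"], ds.counts)
        _write_mtx(paths["spliced"], ds.spliced)
        _write_mtx(paths["unspliced"], ds.unspliced)
        pd.DataFrame({"gene_id": ds.gene_ids, "gene_name": ds.gene_ids}).to_csv(
            paths["features"], sep="\t", header=False, index=False
        )
        pd.Series(ds.cell_ids).to_csv(paths["barcodes"], header=False, index=False)
        pd.DataFrame(
            {
                "barcode": ds.cell_ids,
                "group": ds.cell_groups,
                "true_program": ds.true_program,
            }
        ).to_csv(paths["cells"], sep="\t", index=False)
        write_gmt(ds.program_gene_sets(), paths["gmt"], description="planted")
    except OSError as exc:
        raise OSError(f"failed writing dataset under {out}: {exc}") from exc
    logger.info("wrote synthetic dataset (%d cells x %d genes) to %s",
                ds.n_cells, ds.n_genes, out)
    return paths
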