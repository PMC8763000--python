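"""Spot-module segmentation of expression portraits.

A "spot" is a connected region of overexpressed metagenes in a portrait:
units whose value exceeds the portrait's 90% quantile (strictly — a
constant portrait yields no spots) are marked and partitioned into
8-connected components; small components are discarded and the rest are
labeled A, B, C, ... in order of decreasing total portrait mass.  A
spot's genes are the union of its units' member genes, so spots are the
gene modules whose coordinated overexpression defines a cell state.
Atlases from several portraits (e.g. per-cluster mean portraits) can be
merged into a shared nomenclature by fusing spots with substantial unit
overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._gmt import write_gmt
from .prep import ExpressionMatrix
from .som import Portrait, SOMModel

logger = logging.getLogger(__name__)

_EIGHT_CONN = np.ones((3, 3), dtype=int)


def _letters(i: int) -> str:
    """0 -> A, 1 -> B, ..., 25 -> Z, 26 -> AA, ..."""
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


@dataclass
class Spot:
    """One connected overexpression module."""

    label: str
    units: np.ndarray  # flat unit indices, sorted
    genes: list[str]
    mass: float  # total portrait value over the spot's units
    source_portrait: str

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class SpotAtlas:
    """Spots detected in one portrait (or merged across portraits)."""

    spots: list[Spot]
    grid_shape: tuple[int, int]
    threshold: float
    min_units: int
    unit_genes: dict[int, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for s in self.spots:
            if seen.intersection(s.units.tolist()):
                raise ValueError("spots must be pairwise unit-disjoint")
            seen.update(s.units.tolist())

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spots]

    def gene_sets(self) -> dict[str, list[str]]:
        return {s.label: list(s.genes) for s in self.spots}

    def unit_mask(self) -> np.ndarray:
        """Grid of spot indices (1-based); 0 marks background units."""
        mask = np.zeros(self.grid_shape, dtype=int)
        for i, s in enumerate(self.spots, start=1):
            r, c = np.unravel_index(s.units, self.grid_shape)
            mask[r, c] = i
        return mask

    def save(self, out_dir) -> None:
        """Write spots.tsv, spot_genes.gmt and the unit-mask matrix."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [(s.label, s.n_units, s.n_genes, s.mass) for s in self.spots],
            columns=["label", "n_units", "n_genes", "mass"],
        ).to_csv(out / "spots.tsv", sep="\t", index=False)
        write_gmt(self.gene_sets(), out / "spot_genes.gmt", description="spot")
        np.savetxt(out / "unit_mask.tsv", self.unit_mask(), fmt="%d", delimiter="\t")


def detect_spots(
    p: Portrait,
    model: SOMModel,
    threshold: float = 0.90,
    min_units: int = 4,
) -> SpotAtlas:
    """Segment overexpression spots from one portrait.

    Units strictly above the ``threshold`` quantile of the portrait's unit
    values are grouped into 8-connected components; components smaller
    than ``min_units`` are dropped.  Spots are labeled A, B, ... by
    decreasing total portrait mass.  An empty atlas (nothing above
    threshold) is a valid result.
    """
    if p.grid_shape != model.grid_shape:
        raise ValueError("portrait grid does not match model grid")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold quantile must lie in (0, 1)")
    q = np.quantile(p.values, threshold)
    marked = p.values > q
    labeled, n_comp = ndimage.label(marked, structure=_EIGHT_CONN)

    members = np.array([len(m) for m in model.unit_members], dtype=int)
    candidates = []
    for comp in range(1, n_comp + 1):
        rr, cc = np.nonzero(labeled == comp)
        if len(rr) < min_units:
            continue
        units = np.sort(np.ravel_multi_index((rr, cc), p.grid_shape))
        mass = float(p.values.ravel()[units].sum())
        genes: list[str] = []
        for u in units:
            genes.extend(model.unit_members[u])
        candidates.append((mass, units, genes))
    candidates.sort(key=lambda t: -t[0])

    spots = [
        Spot(label=_letters(i), units=units, genes=genes, mass=mass,
             source_portrait=p.subject)
        for i, (mass, units, genes) in enumerate(candidates)
    ]
    unit_genes = {int(u): list(model.unit_members[u])
                  for s in spots for u in s.units}
    logger.info("detected %d spot(s) in portrait %s (threshold q%.2f)",
                len(spots), p.subject, threshold)
    return SpotAtlas(spots=spots, grid_shape=p.grid_shape, threshold=threshold,
                     min_units=min_units, unit_genes=unit_genes)


def merge_atlases(atlases: list[SpotAtlas], jaccard_cutoff: float = 0.25) -> SpotAtlas:
    """Fuse spot atlases from several portraits into one nomenclature.

    Spots whose unit sets overlap with Jaccard index above
    ``jaccard_cutoff`` are merged transitively (unit union, genes
    recomputed from the union); the merged spots are relabeled A, B, ...
    by decreasing mass, where a merged spot's mass is the maximum over its
    constituents (masses from different portraits are not additive).
    """
    if not atlases:
        raise ValueError("merge_atlases requires at least one atlas")
    shape = atlases[0].grid_shape
    if any(a.grid_shape != shape for a in atlases):
        raise ValueError("atlases are on different grids")

    all_spots = [s for a in atlases for s in a.spots]
    unit_genes: dict[int, list[str]] = {}
    for a in atlases:
        unit_genes.update(a.unit_genes)

    # union-find over spots
    parent = list(range(len(all_spots)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sets = [set(s.units.tolist()) for s in all_spots]
    for i in range(len(all_spots)):
        for j in range(i + 1, len(all_spots)):
            inter = len(sets[i] & sets[j])
            if inter == 0:
                continue
            jac = inter / len(sets[i] | sets[j])
            if jac > jaccard_cutoff:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(all_spots)):
        groups.setdefault(find(i), []).append(i)

    merged = []
    for idxs in groups.values():
        units = np.array(sorted(set().union(*(sets[i] for i in idxs))), dtype=int)
        mass = max(all_spots[i].mass for i in idxs)
        genes = sorted({g for u in units for g in unit_genes.get(int(u), [])})
        sources = ",".join(sorted({all_spots[i].source_portrait for i in idxs}))
        merged.append((mass, units, genes, sources))
    merged.sort(key=lambda t: -t[0])

    # spot pairs below the merge cutoff may still share a few units;
    # contested units go to the more massive spot so the atlas stays disjoint
    claimed: set[int] = set()
    spots = []
    for mass, units, genes, sources in merged:
        free = np.array([u for u in units if int(u) not in claimed], dtype=int)
        if free.size == 0:
            continue
        claimed.update(free.tolist())
        genes = sorted({g for u in free for g in unit_genes.get(int(u), [])})
        spots.append(Spot(label=_letters(len(spots)), units=free, genes=genes,
                          mass=mass, source_portrait=sources))
    return SpotAtlas(spots=spots, grid_shape=shape,
                     threshold=atlases[0].threshold,
                     min_units=min(a.min_units for a in atlases),
                     unit_genes=unit_genes)


def spot_profiles(atlas: SpotAtlas, m: ExpressionMatrix) -> pd.DataFrame:
    """Per-cell mean log expression of each spot's genes (cells x spots)."""
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    out = pd.DataFrame(index=pd.Index(m.cell_ids, name="cell_id"))
    for s in atlas.spots:
        idx = []
        for g in s.genes:
            if g not in gene_pos:
                raise KeyError(f"spot {s.label} gene {g!r} absent from matrix")
            idx.append(gene_pos[g])
        if not idx:
            logger.warning("spot %s has no genes; profile set to NaN", s.label)
            out[s.label] = np.nan
            continue
        out[s.label] = m.values[:, idx].mean(axis=1)
    return out
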