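"""Supporting maps of SOM space and difference portraits.

Beyond per-cell portraits, the metagene grid supports summary views: a
variance map (which regions of the map vary most across cells), an
overexpression summary map (the union of each group's red spots, overlaid
by taking per-unit maxima of thresholded group portraits), pairwise
correlation between grid regions, and difference portraits between
conditions (e.g. each resistance state minus the sensitive state).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .som import Portrait, SOMModel

logger = logging.getLogger(__name__)


@dataclass
class SupportMap:
    values: np.ndarray
    kind: str  # variance | summary | correlation-derived

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("support map values must be 2-D")


def variance_map(model: SOMModel) -> SupportMap:
    """Per-unit variance of the codebook profile across cells."""
    var = model.codebook.var(axis=1).reshape(model.grid_shape)
    return SupportMap(values=var, kind="variance")


def summary_map(portraits: dict[str, Portrait] | list[Portrait],
                threshold: float = 0.90) -> SupportMap:
    """Overlay of group-specific overexpression regions.

    Each portrait keeps only units above its own ``threshold`` quantile
    (per-portrait thresholds, since group portraits differ in scale); the
    summary is the per-unit maximum of the thresholded portraits.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold quantile must lie in (0, 1)")
    items = list(portraits.values()) if isinstance(portraits, dict) else list(portraits)
    if not items:
        raise ValueError("summary_map requires at least one portrait")
    shape = items[0].grid_shape
    acc = np.zeros(shape)
    for p in items:
        if p.grid_shape != shape:
            raise ValueError("portraits are on different grids")
        q = np.quantile(p.values, threshold)
        acc = np.maximum(acc, np.where(p.values > q, p.values, 0.0))
    return SupportMap(values=acc, kind="summary")


def metagene_correlation(model: SOMModel, regions: list) -> np.ndarray:
    """Pearson correlation between region-mean codebook profiles.

    ``regions`` is a list of unit-index collections (flat indices, or
    (row, col) pairs).  A region whose mean profile has zero variance
    yields NaN against every other region.
    """
    profiles = []
    for region in regions:
        units = _as_unit_indices(region, model.grid_shape)
        if units.size == 0:
            raise ValueError("regions must be nonempty")
        profiles.append(model.codebook[units].mean(axis=0))
    P = np.vstack(profiles)
    sd = P.std(axis=1)
    n = len(P)
    corr = np.full((n, n), np.nan)
    ok = sd > 0
    if not ok.all():
        logger.warning("%d region(s) have zero-variance profiles; correlations set to NaN",
                       int((~ok).sum()))
    if ok.any():
        sub = np.corrcoef(P[ok])
        corr[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(corr, np.where(ok, 1.0, np.nan))
    return corr


def _as_unit_indices(region, grid_shape: tuple[int, int]) -> np.ndarray:
    arr = np.asarray(list(region))
    if arr.ndim == 2 and arr.shape[1] == 2:
        return np.ravel_multi_index((arr[:, 0], arr[:, 1]), grid_shape)
    return arr.astype(int).ravel()


def difference_portrait(a: Portrait, b: Portrait) -> Portrait:
    """Elementwise ``a - b``: up- and down-regulated regions of a vs b."""
    if a.grid_shape != b.grid_shape:
        raise ValueError(f"grid mismatch: {a.grid_shape} vs {b.grid_shape}")
    return Portrait(values=a.values - b.values,
                    subject=f"{a.subject} - {b.subject}", kind="difference")


def plot_portrait(p: Portrait | SupportMap, path, symmetric: bool = True,
                  cmap: str = "RdBu_r") -> None:
    """Save a portrait/map heatmap as PNG (red = over-, blue = under-expressed)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = p.values
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    if symmetric:
        vmax = np.abs(values).max() or 1.0
        im = ax.imshow(values, cmap=cmap, vmin=-vmax, vmax=vmax)
    else:
        im = ax.imshow(values, cmap=cmap)
    ax.set_xticks([])
    ax.set_yticks([])
    title = getattr(p, "subject", None) or getattr(p, "kind", "")
    ax.set_title(str(title), fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
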