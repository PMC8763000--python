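"""Transcriptional states: portrait clustering, composition, diversity,
signature scoring and group comparisons.

Cells are clustered on their flattened portraits (correlation distance,
average-linkage agglomeration); the number of states is either fixed or
selected by the silhouette maximum over a candidate range.  State-by-group
composition tables quantify how treatment redistributes cells among
states, and their Shannon entropy (natural log) is the alpha diversity of
a group's state repertoire — 0 when a group occupies a single state,
ln(k) when it spreads uniformly over k states.  Gene-set signatures
(cell-cycle phases, lineage programs, externally published sets from GMT
files) are scored as the per-cell mean of the member genes' centralized
log expression and compared across groups with one-way ANOVA plus Tukey's
honest-significant-difference post hoc test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._gmt import read_gmt, write_gmt  # re-exported
from .prep import ExpressionMatrix
from .som import Portrait, SOMModel, mean_portrait

__all__ = [
    "ClusterAssignment", "CompositionTable", "DiversityResult", "GeneSet",
    "cluster_portraits", "composition", "alpha_diversity", "diversity",
    "score_signature", "compare_groups", "read_gmt", "write_gmt",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """State label per cell plus per-state centroid portraits."""

    labels: np.ndarray  # "C1".."Ck" per cell, C1 = largest state
    k: int
    method: str
    centroids: dict[str, Portrait] = field(repr=False)
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def indices(self, state: str) -> np.ndarray:
        return np.flatnonzero(self.labels == state)


@dataclass
class CompositionTable:
    """State x group cross-tabulation with row/column fractions."""

    counts: pd.DataFrame  # states x groups, ints

    @property
    def n_cells(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_fractions(self) -> pd.DataFrame:
        """Distribution of treatment groups within each state."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    @property
    def col_fractions(self) -> pd.DataFrame:
        """Distribution of states within each treatment group."""
        return self.counts.div(self.counts.sum(axis=0), axis=1)


@dataclass
class DiversityResult:
    """Alpha diversity (Shannon entropy, natural log) per group and state."""

    per_group: pd.Series  # entropy of state composition within each group
    per_state: pd.Series  # entropy of group composition within each state


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    direction: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate ids")


def load_gene_sets(path) -> list[GeneSet]:
    """Read a GMT file into :class:`GeneSet` objects."""
    return [GeneSet(name=n, genes=g) for n, g in read_gmt(path).items()]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _portrait_matrix(model: SOMModel, cells: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(model.n_cells) if cells is None else np.asarray(list(cells), dtype=int)
    return model.codebook[:, idx].T.copy(), idx  # cells x units


def _correlation_distance(P: np.ndarray) -> np.ndarray:
    Z = P - P.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Z, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    Z /= norm
    corr = np.clip(Z @ Z.T, -1.0, 1.0)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def cluster_portraits(
    model: SOMModel,
    cells: np.ndarray | None = None,
    k: int | str = "auto",
    k_range: tuple[int, int] = (2, 12),
    method: str = "agglomerative",
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster cells on their flattened portrait vectors.

    Correlation distance with average-linkage agglomeration by default
    (deterministic); ``k="auto"`` picks the silhouette maximum over
    ``k_range`` (ties go to the smaller k).  A seeded k-means fallback on
    the raw portrait vectors is available as ``method="kmeans"``.
    States are relabeled C1, C2, ... by decreasing size.
    """
    P, idx = _portrait_matrix(model, cells)
    n = len(idx)
    if isinstance(k, int) and k > n:
        raise ValueError(f"k={k} exceeds {n} cells")

    candidates = ([k] if isinstance(k, int)
                  else list(range(k_range[0], min(k_range[1], n - 1) + 1)))

    sil: dict[int, float] = {}
    if method == "agglomerative":
        D = _correlation_distance(P)
        Z = hierarchy.linkage(squareform(D, checks=False), method="average")
        labelings = {kk: hierarchy.fcluster(Z, kk, criterion="maxclust")
                     for kk in candidates}
        if len(candidates) > 1:
            for kk, lab in labelings.items():
                if len(np.unique(lab)) < 2:
                    continue
                sil[kk] = float(silhouette_score(D, lab, metric="precomputed"))
            best = max(sil, key=lambda kk: (sil[kk], -kk))
        else:
            best = candidates[0]
        raw = labelings[best]
    elif method == "kmeans":
        labelings = {}
        for kk in candidates:
            km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(P)
            labelings[kk] = km.labels_ + 1
            if len(candidates) > 1 and len(np.unique(km.labels_)) > 1:
                sil[kk] = float(silhouette_score(P, km.labels_))
        best = max(sil, key=lambda kk: (sil[kk], -kk)) if len(candidates) > 1 else candidates[0]
        raw = labelings[best]
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    # relabel by decreasing state size: C1 is the largest
    sizes = pd.Series(raw).value_counts()
    remap = {old: f"C{i + 1}" for i, old in enumerate(sizes.index)}
    labels = np.array([remap[v] for v in raw], dtype=object)
    k_final = len(sizes)
    centroids = {
        state: mean_portrait(model, idx[labels == state], subject=state)
        for state in sorted(remap.values(), key=lambda s: int(s[1:]))
    }
    logger.info("portrait clustering: k=%d (%s)", k_final, method)
    return ClusterAssignment(labels=labels, k=k_final, method=method,
                             centroids=centroids, silhouette_by_k=sil)


# ---------------------------------------------------------------------------
# composition & diversity
# ---------------------------------------------------------------------------

def composition(assign: ClusterAssignment | np.ndarray, groups: np.ndarray) -> CompositionTable:
    """Cross-tabulate state labels against treatment groups."""
    labels = assign.labels if isinstance(assign, ClusterAssignment) else np.asarray(assign)
    groups = np.asarray(groups)
    if len(labels) != len(groups):
        raise ValueError("state and group label lengths differ")
    counts = pd.crosstab(pd.Series(labels, name="state"),
                         pd.Series(groups, name="group"))
    return CompositionTable(counts=counts)


def alpha_diversity(fracs) -> float:
    """Shannon entropy H = -sum p ln p of a composition vector.

    Zero entries contribute 0; H ranges from 0 (single category) to
    ln(number of categories) (uniform).
    """
    p = np.asarray(fracs, dtype=float)
    if np.any(p < 0):
        raise ValueError("fractions must be nonnegative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"fractions must sum to 1 (got {total})")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def diversity(table: CompositionTable) -> DiversityResult:
    """Alpha diversity per group (over states) and per state (over groups)."""
    col = table.col_fractions
    row = table.row_fractions
    per_group = pd.Series(
        {g: alpha_diversity(col[g].to_numpy()) for g in col.columns}, name="H")
    per_state = pd.Series(
        {s: alpha_diversity(row.loc[s].to_numpy()) for s in row.index}, name="H")
    return DiversityResult(per_group=per_group, per_state=per_state)


# ---------------------------------------------------------------------------
# signatures & tests
# ---------------------------------------------------------------------------

def score_signature(m: ExpressionMatrix, gs: GeneSet) -> np.ndarray:
    """Per-cell mean (log, centralized) expression of the set's genes.

    Genes absent from the matrix are dropped with a warning; an empty
    overlap is an error.
    """
    present = [g for g in gs.genes if g in set(m.gene_ids)]
    missing = len(gs.genes) - len(present)
    if not present:
        raise ValueError(f"no genes of set {gs.name!r} are present in the matrix")
    if missing:
        logger.warning("signature %s: %d/%d genes absent from matrix",
                       gs.name, missing, len(gs.genes))
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    idx = [pos[g] for g in present]
    return m.values[:, idx].mean(axis=1)


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD post hoc."""

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, p_adj, significant
    alpha: float = 0.05


def compare_groups(scores: np.ndarray, labels: np.ndarray,
                   alpha: float = 0.05) -> GroupComparison:
    """ANOVA F-test across groups plus all-pairs Tukey HSD."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels lengths differ")
    group_names = list(pd.unique(labels))
    samples = [scores[labels == g] for g in group_names]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("compare_groups needs >= 2 groups with >= 2 cells each")
    f_stat, p_val = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            p_adj = float(tukey.pvalue[i, j])
            rows.append((group_names[i], group_names[j], p_adj, p_adj < alpha))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "p_adj", "significant"])
    return GroupComparison(f_statistic=float(f_stat), p_value=float(p_val),
                           pairwise=pairwise, alpha=alpha)
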