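"""Cell-cell distances on high-Gini genes and density-based cluster detection.

Clustering is deliberately restricted to the selected high-Gini genes: rare
subpopulations differ from the bulk in exactly those features, while most
other genes only add noise.  Two metrics are supported, matching the two data
modalities: Jaccard distance on binarized detection patterns (robust to the
strong dropout noise of RNA-seq counts) and one-minus-Pearson-correlation on
qPCR expression, which is quantitative over a wide dynamic range.

Clusters are found with DBSCAN on the precomputed distance matrix.  Cells in
no dense neighbourhood are *singletons* — outliers that do not share their
expression pattern with enough other cells to constitute a cluster — and a
detected cluster is flagged *rare* when it holds less than 5 % of all cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "jaccard_distance",
    "correlation_distance",
    "dbscan",
    "ClusterAssignment",
    "RARE_FRACTION",
    "SINGLETON",
]

#: a cluster is rare when its size is below this fraction of all cells
RARE_FRACTION = 0.05
#: label used for unassigned (noise) cells
SINGLETON = -1


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels plus per-cluster bookkeeping.

    ``labels[i]`` is a 1-based cluster id or :data:`SINGLETON` (-1).  Ids are
    assigned by decreasing cluster size, so cluster 1 is always the largest;
    rare clusters sort to the end.
    """

    cell_names: list[str]
    labels: np.ndarray
    rare_fraction: float = RARE_FRACTION
    sizes: dict[int, int] = field(init=False)
    rare_ids: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.cell_names) != self.labels.size:
            raise ValueError("labels and cell_names length mismatch")
        ids, counts = np.unique(self.labels[self.labels != SINGLETON], return_counts=True)
        self.sizes = {int(i): int(c) for i, c in zip(ids, counts)}
        cutoff = self.rare_fraction * self.labels.size
        self.rare_ids = [i for i, c in self.sizes.items() if c < cutoff]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def n_singletons(self) -> int:
        return int((self.labels == SINGLETON).sum())

    def members(self, cluster_id: int) -> list[str]:
        return [c for c, l in zip(self.cell_names, self.labels) if l == cluster_id]

    def to_frame(self) -> pd.DataFrame:
        lab = ["SINGLETON" if l == SINGLETON else str(l) for l in self.labels]
        return pd.DataFrame({"cell": self.cell_names, "cluster": lab})

    def summary(self) -> pd.DataFrame:
        rows = [
            {"cluster": i, "size": self.sizes[i], "rare": i in self.rare_ids}
            for i in sorted(self.sizes)
        ]
        return pd.DataFrame(rows, columns=["cluster", "size", "rare"])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def jaccard_distance(values: np.ndarray) -> np.ndarray:
    """Jaccard distance between cells on binarized detection patterns.

    ``values`` is genes-by-cells; a gene counts as detected in a cell when its
    value is strictly positive.  ``d(a, b) = 1 - |A & B| / |A | B|`` over the
    detected-gene sets.  Two cells that both detect nothing are at distance 0
    (identical emptiness); empty versus nonempty is 1.
    """
    values = np.asarray(values)
    if values.shape[0] < 2:
        raise ValueError("need at least two genes for the Jaccard distance")
    detected = (values > 0).T  # cells x genes, boolean
    empty = ~detected.any(axis=1)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} cell(s) detect none of the selected genes; "
            "their mutual distances are 0", stacklevel=2,
        )
    d = squareform(pdist(detected, metric="jaccard"))
    np.fill_diagonal(d, 0.0)
    return d


def correlation_distance(values: np.ndarray, rescale: bool = True) -> np.ndarray:
    """One-minus-Pearson-correlation distance between cells.

    Raw ``1 - r`` lives on [0, 2]; by default it is halved onto [0, 1] so
    that eps thresholds for both supported metrics live on the same scale.
    Pass ``rescale=False`` for the raw ``1 - r``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least three genes for the correlation distance")
    sd = values.std(axis=0)
    if (sd <= 0).any():
        bad = list(np.flatnonzero(sd <= 0))
        raise ValueError(
            f"cells with zero variance across selected genes: indices {bad}"
        )
    r = np.corrcoef(values.T)
    d = 1.0 - r
    if rescale:
        d = d / 2.0
    d = np.clip(d, 0.0, None)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# DBSCAN on a precomputed distance matrix
# ---------------------------------------------------------------------------

def dbscan(
    dist: np.ndarray,
    eps: float,
    min_pts: int,
    cell_names: list[str] | None = None,
    rare_fraction: float = RARE_FRACTION,
) -> ClusterAssignment:
    """DBSCAN on a precomputed symmetric distance matrix.

    A point is a *core* point when at least ``min_pts`` points (itself
    included) lie within ``eps``; clusters are the connected components of
    core points at distance <= eps, plus border points within eps of a core
    point.  Everything else is a singleton.

    Border points reachable from several clusters are handled
    deterministically, unlike textbook scan-order DBSCAN: such a point joins
    the cluster of its nearest core point, with ties going to the larger
    cluster (then to the cluster containing the lowest-index core point).
    Labels are therefore invariant to the ordering of the input cells.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be at least 1")
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if cell_names is None:
        cell_names = [f"cell{i}" for i in range(n)]

    within = dist <= eps
    np.fill_diagonal(within, True)
    core = within.sum(axis=1) >= min_pts
    labels = np.full(n, SINGLETON, dtype=int)

    core_idx = np.flatnonzero(core)
    if core_idx.size:
        adj = sparse.csr_matrix(within[np.ix_(core_idx, core_idx)])
        _, comp = connected_components(adj, directed=False)
        labels[core_idx] = comp
        comp_sizes = np.bincount(comp)
        # order-invariant identifier per component: lexicographically smallest
        # member cell name (permuting the cells permutes names identically)
        comp_key = {
            c: min(cell_names[i] for i in core_idx[comp == c])
            for c in np.unique(comp)
        }

        # border points: non-core cells within eps of >= 1 core point
        border = np.flatnonzero(~core & within[:, core_idx].any(axis=1))
        for i in border:
            reach = core_idx[within[i, core_idx]]
            # nearest core; ties -> larger cluster, then stable name key
            order = sorted(
                reach,
                key=lambda j: (dist[i, j], -comp_sizes[labels[j]], comp_key[labels[j]]),
            )
            labels[i] = labels[order[0]]

    labels = _renumber_by_size(labels, cell_names)
    return ClusterAssignment(cell_names, labels, rare_fraction)


def _renumber_by_size(labels: np.ndarray, cell_names: list[str]) -> np.ndarray:
    """Relabel clusters 1..K by decreasing size.

    Equal-size clusters are ordered by their lexicographically smallest member
    name, so the numbering does not depend on input cell order.
    """
    ids = np.unique(labels[labels != SINGLETON])
    keyed = [
        (
            -int((labels == i).sum()),
            min(n for n, l in zip(cell_names, labels) if l == i),
            i,
        )
        for i in ids
    ]
    mapping = {old: new for new, (_, _, old) in enumerate(sorted(keyed), start=1)}
    out = labels.copy()
    for old, new in mapping.items():
        out[labels == old] = new
    return out
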