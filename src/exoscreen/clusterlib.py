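"""Distance matrices and clustering shared by the 2D and 3D comparison arms.

The workflow compares structures pairwise — dot-bracket strings by
Levenshtein edit distance, tertiary structures by superposition RMSD — and
clusters the resulting symmetric matrix.  The 2D arm uses DBSCAN (density
clustering with explicit noise); the 3D arm uses single-linkage
agglomeration with either an explicit distance threshold or an automatic
largest-gap cut, plus medoid-style centroid selection within clusters.

Edit distances are computed with the edlib alignment library; DBSCAN runs on
scikit-learn with a precomputed matrix; single-linkage merge heights come
from scipy's hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import edlib
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from sklearn.cluster import DBSCAN

from .errors import CoordinateError, MetricViolationError

#: Marker for DBSCAN noise points in :class:`ClusterResult.assignments`.
NOISE = 0


@dataclass(frozen=True)
class DistanceMatrix:
    """A labeled symmetric distance matrix (edits for 2D, Å for 3D)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise MetricViolationError("distances must be finite and non-negative")
        if np.any(np.diag(v) != 0):
            raise MetricViolationError("diagonal must be exactly zero")
        if not np.array_equal(v, v.T):
            raise MetricViolationError("matrix must be exactly symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise CoordinateError(f"unknown item {label!r}") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, members: Iterable[str]) -> "DistanceMatrix":
        idx = [self.index(m) for m in members]
        return DistanceMatrix(
            labels=tuple(self.labels[i] for i in idx),
            values=self.values[np.ix_(idx, idx)],
        )


@dataclass(frozen=True)
class ClusterParams:
    """Parameters for the two clustering back-ends.

    ``eps``/``min_samples`` drive DBSCAN; ``cut`` drives single linkage and
    is either an explicit distance threshold or the string ``"largest-gap"``
    (cut at the widest gap between consecutive sorted merge heights).
    """

    eps: float = 4.0
    min_samples: int = 2
    cut: float | str = "largest-gap"

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if isinstance(self.cut, str) and self.cut != "largest-gap":
            raise ValueError(f"unknown cut rule {self.cut!r}")


@dataclass(frozen=True)
class ClusterResult:
    """A partition: item -> cluster id (>= 1), with DBSCAN noise marked 0.

    Cluster ids are contiguous from 1, ordered by the position of each
    cluster's first member in the input label order.  ``n_clusters`` excludes
    noise.
    """

    assignments: dict[str, int]
    n_clusters: int
    members: dict[int, tuple[str, ...]]
    noise: tuple[str, ...] = ()

    def cluster_of(self, label: str) -> int:
        return self.assignments[label]

    def largest_cluster(self) -> tuple[int, tuple[str, ...]]:
        cid = max(self.members, key=lambda c: (len(self.members[c]), -c))
        return cid, self.members[cid]

    def noise_as_singletons(self) -> "ClusterResult":
        """Convert each noise point to its own singleton cluster."""
        if not self.noise:
            return self
        assignments = dict(self.assignments)
        members = {c: m for c, m in self.members.items()}
        next_id = self.n_clusters + 1
        for label in self.noise:
            assignments[label] = next_id
            members[next_id] = (label,)
            next_id += 1
        return ClusterResult(assignments, next_id - 1, members, noise=())


def _relabel(labels: tuple[str, ...], raw: np.ndarray) -> ClusterResult:
    """Renumber raw integer assignments (noise < 0) into a ClusterResult."""
    order: dict[int, int] = {}
    for lab, r in zip(labels, raw):
        if r >= 0 and r not in order:
            order[r] = len(order) + 1
    assignments = {
        lab: (order[r] if r >= 0 else NOISE) for lab, r in zip(labels, raw)
    }
    members = {
        cid: tuple(lab for lab in labels if assignments[lab] == cid)
        for cid in sorted(order.values())
    }
    noise = tuple(lab for lab in labels if assignments[lab] == NOISE)
    return ClusterResult(assignments, len(order), members, noise)


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def pairwise_distances(
    items: dict[str, str] | list[tuple[str, str]],
    metric: Callable[[str, str], float] = levenshtein,
) -> DistanceMatrix:
    """Evaluate a metric once per unordered pair of labeled items."""
    pairs = list(items.items()) if isinstance(items, dict) else list(items)
    if not pairs:
        raise ValueError("at least one item required")
    labels = tuple(lab for lab, _ in pairs)
    n = len(pairs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(metric(pairs[i][1], pairs[j][1]))
            if not np.isfinite(d) or d < 0:
                raise MetricViolationError(
                    f"metric returned {d!r} for ({labels[i]!r}, {labels[j]!r})"
                )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


def dbscan(D: DistanceMatrix, p: ClusterParams) -> ClusterResult:
    """Density clustering over the precomputed matrix.

    Core points have at least ``min_samples`` neighbors within ``eps``
    (inclusive radius, self included); clusters are the connected components
    of core points plus their border points; remaining points are noise
    (marked :data:`NOISE`, excluded from ``n_clusters``).
    """
    model = DBSCAN(eps=p.eps, min_samples=p.min_samples, metric="precomputed")
    raw = model.fit_predict(D.values)
    return _relabel(D.labels, raw)


def single_linkage(D: DistanceMatrix, p: ClusterParams) -> ClusterResult:
    """Single-linkage agglomeration with threshold or largest-gap cut.

    At an explicit threshold t the partition is exactly the connected
    components of the graph with edges strictly below t (the defining
    property of single linkage).  With ``cut="largest-gap"`` the merge
    heights from the dendrogram are sorted and the cut is placed in the
    middle of the widest gap between consecutive heights; when all heights
    are equal (no gap) everything stays in one cluster, and gap ties resolve
    toward fewer clusters.
    """
    if D.n == 1:
        return _relabel(D.labels, np.array([0]))
    if isinstance(p.cut, str):  # largest-gap
        Z = linkage(squareform(D.values, checks=False), method="single")
        heights = np.sort(Z[:, 2])
        gaps = np.diff(heights)
        if len(gaps) == 0 or np.max(gaps) <= 0:
            return _relabel(D.labels, np.zeros(D.n, dtype=int))
        # ties toward fewer clusters: take the last argmax (highest cut)
        g = len(gaps) - 1 - int(np.argmax(gaps[::-1]))
        # split only on a genuine scale separation: the merge height above
        # the gap must at least double the height below it, otherwise the
        # "gap" is noise within one scale and everything stays together
        if heights[g + 1] < 2.0 * heights[g]:
            return _relabel(D.labels, np.zeros(D.n, dtype=int))
        threshold = (heights[g] + heights[g + 1]) / 2.0
    else:
        threshold = float(p.cut)
    adj = csr_matrix(D.values < threshold)
    _, comp = connected_components(adj, directed=False)
    return _relabel(D.labels, comp)


def centroid(D: DistanceMatrix, members: Iterable[str]) -> tuple[str, float, float]:
    """Medoid of a member set: the item minimizing mean distance to the rest.

    Returns (centroid label, average distance to the centroid, population
    standard deviation), both computed over the non-centroid members only —
    so a two-member cluster reports its single pairwise distance, not half of
    it.  A singleton returns (itself, 0.0, 0.0).  Ties resolve toward the
    member earliest in the matrix label order.
    """
    members = list(members)
    if not members:
        raise ValueError("members must be non-empty")
    idx = [D.index(m) for m in members]
    if len(idx) == 1:
        return members[0], 0.0, 0.0
    sub = D.values[np.ix_(idx, idx)]
    means = sub.sum(axis=1) / (len(idx) - 1)
    best = int(np.lexsort((idx, means))[0])
    others = np.delete(sub[best], best)
    return members[best], float(others.mean()), float(others.std())


# ---------------------------------------------------------------------------
# I/O

def write_distance_matrix(D: DistanceMatrix, path: str | Path, header_lines=None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("\t" + "\t".join(D.labels) + "\n")
        for lab, row in zip(D.labels, D.values):
            fh.write(lab + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    lines = [
        ln for ln in Path(path).read_text().splitlines() if not ln.startswith("#")
    ]
    labels = tuple(lines[0].lstrip("\t").split("\t"))
    values = np.array(
        [[float(v) for v in ln.split("\t")[1:]] for ln in lines[1 : len(labels) + 1]]
    )
    return DistanceMatrix(labels, values)


def write_assignments(result: ClusterResult, path: str | Path, header_lines=None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("item\tcluster\n")
        for item in result.assignments:
            cid = result.assignments[item]
            fh.write(f"{item}\t{cid if cid != NOISE else 'noise'}\n")
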