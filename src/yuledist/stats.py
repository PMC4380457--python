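"""Distance-matrix statistics: the tree-free analysis path.

Everything here operates on a bare symmetric matrix of pairwise time
distances, which is all the empirical pipeline has (no tree reconstruction is
required).  The four statistics mirror the analytic density families:
all pairwise distances, per-leaf n-th nearest distances, cherries
(reciprocal nearest pairs) and the per-pair minimum of nearest distances.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import FormatError, ParameterError
from .params import PairStatisticKind

__all__ = [
    "DistanceMatrix",
    "DistanceHistogram",
    "pairwise_list",
    "nth_nearest_list",
    "cherry_list",
    "min2_list",
    "build_histogram",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative matrix of pairwise time distances between leaves.

    ``T`` is the tree height; if unknown it is inferred as max(distance)/2,
    since distances on a tree of height T are supported on [0, 2T].
    """

    labels: tuple
    values: np.ndarray
    T: Optional[float] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise FormatError(f"distance matrix must be square, got shape {v.shape}")
        if len(self.labels) != v.shape[0]:
            raise FormatError(
                f"{len(self.labels)} labels for a {v.shape[0]}x{v.shape[0]} matrix")
        if v.size:
            if np.any(np.diag(v) != 0.0):
                raise FormatError("distance matrix diagonal must be exactly zero")
            if np.any(v < 0.0):
                raise FormatError("distances must be nonnegative")
            scale = max(float(np.max(np.abs(v))), 1.0)
            if np.max(np.abs(v - v.T)) > 1e-9 * scale:
                raise FormatError("distance matrix is asymmetric beyond tolerance")
        if self.T is not None and self.T < 0:
            raise ParameterError(f"height must be >= 0, got {self.T}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> float:
        """Tree height T; inferred as max(distance)/2 when not given."""
        if self.T is not None:
            return self.T
        return float(np.max(self.values)) / 2.0 if self.n > 1 else 0.0

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        """Three-point check: for all triples the two largest distances agree."""
        v = self.values
        for i in range(self.n):
            for j in range(i + 1, self.n):
                for k in range(j + 1, self.n):
                    d = sorted((v[i, j], v[i, k], v[j, k]))
                    if d[2] - d[1] > tol * max(d[2], 1e-300):
                        return False
        return True


def pairwise_list(matrix: DistanceMatrix) -> np.ndarray:
    """All M(M-1)/2 upper-triangle distances."""
    iu = np.triu_indices(matrix.n, k=1)
    return matrix.values[iu]


def _nearest(matrix: DistanceMatrix) -> np.ndarray:
    """Each leaf's distance to its nearest neighbour (requires n >= 2)."""
    v = matrix.values.copy()
    np.fill_diagonal(v, np.inf)
    return v.min(axis=1)


def nth_nearest_list(matrix: DistanceMatrix, n: int) -> list:
    """(label, distance to n-th nearest neighbour) for every leaf with >= n others.

    Ties count with multiplicity: the n-th value of the sorted multiset of a
    leaf's off-diagonal row.
    """
    if n < 1 or n != int(n):
        raise ParameterError(f"rank must be a positive integer, got {n}")
    out = []
    if matrix.n <= n:
        return out
    for i in range(matrix.n):
        row = np.delete(matrix.values[i], i)
        row.sort()
        out.append((matrix.labels[i], float(row[n - 1])))
    return out


def cherry_list(matrix: DistanceMatrix) -> list:
    """Reciprocal-nearest pairs (i, j, distance); each leaf in at most one cherry.

    Ties (several equidistant nearest neighbours) are resolved greedily by
    ascending distance, then lexicographic label pair -- deterministic on
    rounded empirical matrices where exact ties do occur.
    """
    if matrix.n < 2:
        return []
    d1 = _nearest(matrix)
    cand = []
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            d = matrix.values[i, j]
            if d == d1[i] and d == d1[j]:
                cand.append((d, matrix.labels[i], matrix.labels[j], i, j))
    cand.sort(key=lambda c: (c[0], c[1], c[2]))
    used = set()
    out = []
    for d, li, lj, i, j in cand:
        if i in used or j in used:
            continue
        used.add(i)
        used.add(j)
        out.append((li, lj, float(d)))
    return out


def min2_list(matrix: DistanceMatrix, T: Optional[float] = None) -> list:
    """Per unordered pair, the smaller of the two members' nearest distances.

    A leaf alone in the tree has nearest distance 2T by convention, but a
    single leaf forms no pair, so the convention only matters upstream (in
    the recursion over subtrees), never in this list.
    """
    if matrix.n < 2:
        return []
    d1 = _nearest(matrix)
    out = []
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            out.append(((matrix.labels[i], matrix.labels[j]), float(min(d1[i], d1[j]))))
    return out


@dataclass(frozen=True)
class DistanceHistogram:
    """Uniformly binned counts of one pair statistic, pooled over trees.

    Bins are half-open [left, right) except the last, which is closed.
    ``density = counts / (bin width * n_trees)``, i.e. a per-tree average
    comparable to the analytic curves.  For simulated ensembles the per-tree
    sum of squares and the number of trees with a nonzero bin count are
    retained, giving standard errors and the conditional (nonzero-bin) mean.
    """

    edges: np.ndarray
    counts: np.ndarray
    n_trees: int = 1
    kind: Optional[PairStatisticKind] = None
    sumsq: Optional[np.ndarray] = None
    nonzero_trees: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "edges", np.asarray(self.edges, float))
        object.__setattr__(self, "counts", np.asarray(self.counts, float))
        if self.edges.ndim != 1 or self.edges.size < 2:
            raise ParameterError("need at least two bin edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if self.counts.shape != (self.edges.size - 1,):
            raise ParameterError("counts length must equal number of bins")
        if self.n_trees < 1:
            raise ParameterError("pooled tree count must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def density(self) -> np.ndarray:
        return self.counts / (self.widths * self.n_trees)

    @property
    def density_se(self) -> Optional[np.ndarray]:
        """Standard error of the per-tree mean density (needs ensemble moments)."""
        if self.sumsq is None:
            return None
        S = self.n_trees
        m1 = self.counts / S
        var = np.maximum(self.sumsq / S - m1 ** 2, 0.0)
        return np.sqrt(var / S) / self.widths

    @property
    def conditional_density(self) -> Optional[np.ndarray]:
        """Mean density over trees with a nonzero count in the bin (Ntilde estimator)."""
        if self.nonzero_trees is None:
            return None
        nz = self.nonzero_trees
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(nz > 0, self.counts / np.maximum(nz, 1), np.nan)
        return out / self.widths

    @property
    def conditional_density_se(self) -> Optional[np.ndarray]:
        if self.nonzero_trees is None or self.sumsq is None:
            return None
        nz = np.maximum(self.nonzero_trees, 1)
        m1 = self.counts / nz
        var = np.maximum(self.sumsq / nz - m1 ** 2, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.where(self.nonzero_trees > 0, np.sqrt(var / nz), np.nan)
        return se / self.widths


def bin_values(values: Sequence[float], edges: np.ndarray,
               weights: Optional[Sequence[float]] = None) -> np.ndarray:
    """Histogram with half-open bins, last bin closed (numpy convention)."""
    return np.histogram(np.asarray(values, float), bins=edges,
                        weights=None if weights is None else np.asarray(weights, float))[0]


def build_histogram(values: Sequence[float],
                    bins: Union[int, np.ndarray] = 50,
                    t_range: Optional[tuple] = None,
                    n_trees: int = 1,
                    kind: Optional[PairStatisticKind] = None) -> DistanceHistogram:
    """Bin statistic values into a DistanceHistogram.

    ``bins`` is a bin count (uniform over ``t_range``, default [0, max value])
    or an explicit edge array.  ``n_trees`` is the number of pooled trees the
    densities are averaged over.
    """
    values = np.asarray(list(values), float)
    if np.isscalar(bins) or np.ndim(bins) == 0:
        nbins = int(bins)
        if nbins < 1:
            raise ParameterError(f"need at least one bin, got {nbins}")
        if t_range is None:
            hi = float(values.max()) if values.size else 1.0
            t_range = (0.0, hi if hi > 0 else 1.0)
        lo, hi = map(float, t_range)
        if hi <= lo:
            raise ParameterError(f"empty bin range [{lo}, {hi}]")
        edges = np.linspace(lo, hi, nbins + 1)
    else:
        edges = np.asarray(bins, float)
    counts = bin_values(values, edges)
    return DistanceHistogram(edges=edges, counts=counts.astype(float),
                             n_trees=n_trees, kind=kind)
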