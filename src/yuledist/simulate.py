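"""Kinetic Monte Carlo simulation of Yule trees with Bernoulli leaf sampling.

``simulate_tree`` returns a :class:`LineageTree` holding the complete event
history (including extinct subtrees, which are excluded from all distance
statistics).  ``ensemble_histograms`` runs many trees through a compiled
kernel and accumulates the pair-statistic histograms the analytic module
predicts, together with per-bin occupancy tallies and leaf-count spectra.

Reproducibility contract: one master seed per run; per-tree substreams are
derived from it by counter (``numpy.random.SeedSequence``), so tree ``i`` of a
run is the same object regardless of how the ensemble is chunked.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from ._kernels import KIND_DEATH, KIND_EXTANT, KIND_SPLIT
from .errors import ContractError, ExplosionError, ParameterError
from .params import PairStatisticKind, YuleParams
from .stats import DistanceHistogram, DistanceMatrix

__all__ = [
    "SimulationConfig",
    "LineageTree",
    "simulate_tree",
    "simulate_forest",
    "pairwise_distance_list",
    "pair_count_occupancy",
    "ensemble_histograms",
    "EnsembleResult",
]

_EVENT_NAMES = {KIND_SPLIT: "split", KIND_DEATH: "death", KIND_EXTANT: "extant"}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters, replicate count, master seed and the explosion guard."""

    params: YuleParams
    n_trees: int = 1
    seed: int = 0
    lineage_cap: int = 10 ** 6

    def __post_init__(self):
        if self.n_trees < 1:
            raise ParameterError(f"replicate count must be >= 1, got {self.n_trees}")
        if self.lineage_cap < 1:
            raise ParameterError(f"lineage cap must be >= 1, got {self.lineage_cap}")

    def tree_seeds(self, n: Optional[int] = None) -> np.ndarray:
        state = np.random.SeedSequence(self.seed).generate_state(n or self.n_trees)
        return state.astype(np.int64)


@dataclass(frozen=True)
class LineageTree:
    """Complete genealogy of one simulated tree.

    Node 0 is the root (born at time 0).  ``t_end`` is the split time, death
    time, or T for extant lineages; children are appended after their parent,
    so ``parent[i] < i`` always holds.  ``observed`` is True only for extant
    leaves that survived Bernoulli(sigma) sampling.
    """

    params: YuleParams
    parent: np.ndarray
    t_birth: np.ndarray
    t_end: np.ndarray
    event: np.ndarray  # int8 codes, see _EVENT_NAMES
    observed: np.ndarray

    @property
    def T(self) -> float:
        return self.params.T

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def event_name(self, i: int) -> str:
        return _EVENT_NAMES[int(self.event[i])]

    @property
    def extant_leaves(self) -> np.ndarray:
        return np.flatnonzero(self.event == KIND_EXTANT)

    @property
    def observed_leaves(self) -> np.ndarray:
        return np.flatnonzero(self.observed)

    @property
    def n_extant(self) -> int:
        return int(np.sum(self.event == KIND_EXTANT))

    @property
    def n_observed(self) -> int:
        return int(np.sum(self.observed))

    # -- genealogy walks ----------------------------------------------------

    def mrca_time(self, i: int, j: int) -> float:
        """Split time of the most recent common ancestor of two distinct leaves."""
        if i == j:
            raise ParameterError("MRCA requires two distinct leaves")
        anc = set()
        node = int(i)
        while node >= 0:
            anc.add(node)
            node = int(self.parent[node])
        node = int(j)
        while node not in anc:
            node = int(self.parent[node])
        return float(self.t_end[node])

    def distance(self, i: int, j: int) -> float:
        """Pairwise time distance 2 (T - t_MRCA) between two leaves."""
        return 2.0 * (self.T - self.mrca_time(i, j))

    def subtree_observed_counts(self) -> np.ndarray:
        return _kernels._obs_counts(self.parent, self.event, self.observed)

    def lineages_with_observed_descendants(self, t: float) -> int:
        """Number of lineages alive at time t with >= 1 observed descendant at T."""
        if not (0.0 <= t <= self.T):
            raise ParameterError(f"t must lie in [0, T], got {t}")
        cnt = self.subtree_observed_counts()
        alive = (self.t_birth <= t) & ((t < self.t_end) |
                                       ((self.t_end == t) & (self.event == KIND_EXTANT)))
        return int(np.sum(alive & (cnt > 0)))

    def distance_matrix(self) -> DistanceMatrix:
        """Cophenetic matrix between observed leaves (labels "L<node id>")."""
        leaves = self.observed_leaves
        m = len(leaves)
        out = np.zeros((m, m))
        # one upward pass per leaf against precomputed ancestor depths
        anc_time: List[dict] = []
        for leaf in leaves:
            d = {}
            node = int(leaf)
            while node >= 0:
                d[node] = float(self.t_end[node])
                node = int(self.parent[node])
            anc_time.append(d)
        for a in range(m):
            for b in range(a + 1, m):
                node = int(leaves[b])
                while node >= 0:
                    if node in anc_time[a] and node not in (int(leaves[a]), int(leaves[b])):
                        out[a, b] = out[b, a] = 2.0 * (self.T - float(self.t_end[node]))
                        break
                    node = int(self.parent[node])
        return DistanceMatrix(tuple(f"L{int(i)}" for i in leaves), out, T=self.T)

    # -- Newick export ------------------------------------------------------

    def to_newick(self, keep_unobserved: bool = False, fmt: str = "%.10g") -> Optional[str]:
        """Ultrametric Newick of the subtree spanned by retained leaves.

        Retained leaves are the observed ones (default) or all extant leaves
        (``keep_unobserved``).  Extinct subtrees are always pruned and
        unifurcations collapsed.  Returns None when no leaf is retained.
        """
        keep_leaf = self.observed.copy()
        if keep_unobserved:
            keep_leaf |= self.event == KIND_EXTANT
        cnt = np.zeros(self.n_nodes, np.int64)
        for i in range(self.n_nodes - 1, -1, -1):
            if keep_leaf[i] and int(self.event[i]) == KIND_EXTANT:
                cnt[i] += 1
            if self.parent[i] >= 0:
                cnt[self.parent[i]] += cnt[i]
        if cnt[0] == 0:
            return None
        children: List[List[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            children[int(self.parent[i])].append(i)

        def build(i: int, t0: float) -> str:
            while True:
                if int(self.event[i]) == KIND_EXTANT:
                    return f"L{i}:{fmt % (self.T - t0)}"
                kept = [c for c in children[i] if cnt[c] > 0]
                if len(kept) == 1:
                    i = kept[0]  # collapse unifurcation, edge still starts at t0
                    continue
                te = float(self.t_end[i])
                inner = ",".join(build(c, te) for c in kept)
                return f"({inner}):{fmt % (te - t0)}"

        return f"({build(0, 0.0)});"


def _tree_from_kernel(params: YuleParams, seed: int, cap: int) -> LineageTree:
    parent, tb, te, kind, obs, ok = _kernels._kmc(
        params.lam, params.mu, params.sigma, params.T, seed, cap)
    if not ok:
        raise ExplosionError(cap)
    return LineageTree(params=params, parent=parent, t_birth=tb, t_end=te,
                       event=kind, observed=obs)


def simulate_tree(config: SimulationConfig, index: int = 0) -> LineageTree:
    """Simulate tree number ``index`` of the configured ensemble."""
    if not (0 <= index < config.n_trees):
        raise ParameterError(f"tree index {index} outside [0, {config.n_trees})")
    seed = int(config.tree_seeds(index + 1)[index])
    return _tree_from_kernel(config.params, seed, config.lineage_cap)


def simulate_forest(config: SimulationConfig) -> List[LineageTree]:
    """All trees of the ensemble as LineageTree objects (memory permitting)."""
    seeds = config.tree_seeds()
    return [_tree_from_kernel(config.params, int(s), config.lineage_cap) for s in seeds]


def pairwise_distance_list(tree: LineageTree) -> List[Tuple[int, int, float]]:
    """(leaf, leaf, 2 (T - t_MRCA)) for every unordered observed pair.

    Found by walking parent links; length M_obs (M_obs - 1)/2.
    """
    leaves = [int(x) for x in tree.observed_leaves]
    out = []
    for a in range(len(leaves)):
        for b in range(a + 1, len(leaves)):
            out.append((leaves[a], leaves[b], tree.distance(leaves[a], leaves[b])))
    return out


@dataclass(frozen=True)
class EnsembleResult:
    """Pooled histograms and tallies from an ensemble run.

    ``histograms`` maps each requested statistic kind to a
    :class:`DistanceHistogram` carrying the pooled mean density (the ensemble
    estimator of the analytic N), the conditional nonzero-bin mean (the
    Ntilde estimator) and per-bin standard errors.  ``occupancy[b, n]``
    counts trees with exactly n pairwise pairs in bin b (last column:
    overflow beyond ``occupancy_max``).
    """

    config: SimulationConfig
    edges: np.ndarray
    histograms: Dict[PairStatisticKind, DistanceHistogram]
    occupancy: np.ndarray
    occupancy_max: int
    observed_leaf_counts: np.ndarray
    extant_leaf_counts: np.ndarray

    def occupancy_frequencies(self, bin_index: int) -> np.ndarray:
        """P(exactly n pairs in bin) estimates, n = 0 .. occupancy_max (+overflow)."""
        return self.occupancy[bin_index] / self.config.n_trees


def pair_count_occupancy(config: SimulationConfig, t: float, dt: float,
                         max_count: int = 1000) -> np.ndarray:
    """Frequencies over trees of the number of observed pairs in [t, t+dt).

    Returns tallies for counts 0 .. max_count plus one overflow slot; the
    empirical counterpart of the small-bin occupancy probabilities.
    """
    if dt <= 0:
        raise ParameterError(f"bin width must be positive, got {dt}")
    p = config.params
    tally, failed = _kernels._interval_occupancy(
        p.lam, p.mu, p.sigma, p.T, config.tree_seeds(), t, t + dt,
        config.lineage_cap, max_count)
    if failed:
        raise ExplosionError(config.lineage_cap)
    return tally


def ensemble_histograms(config: SimulationConfig,
                        kinds: Iterable[PairStatisticKind],
                        bins: int = 50,
                        t_max: Optional[float] = None,
                        occupancy_max: int = 200,
                        leaf_count_max: int = 65535) -> EnsembleResult:
    """Simulate the ensemble and accumulate per-kind distance histograms.

    Bins are uniform over [0, t_max] (default support [0, 2T]).  Deterministic
    given the config seed.
    """
    kinds = list(kinds)
    if not kinds:
        raise ContractError("at least one statistic kind is required")
    ns = sorted({k.n for k in kinds if k.name == "nth_min"})
    hi = float(t_max) if t_max is not None else 2.0 * config.params.T
    if hi <= 0:
        raise ParameterError("histogram range must be positive (is T > 0?)")
    nbins = int(bins)
    if nbins < 1:
        raise ParameterError(f"need at least one bin, got {bins}")
    p = config.params
    sums, sumsq, nonzero, occ, leafh, extanth, failed = _kernels._ensemble(
        p.lam, p.mu, p.sigma, p.T, config.tree_seeds(), nbins, hi,
        np.asarray(ns, np.int64), config.lineage_cap, occupancy_max, leaf_count_max)
    if failed:
        raise ExplosionError(config.lineage_cap)
    edges = np.linspace(0.0, hi, nbins + 1)
    row = {"pairwise": 0, "cherry": 1, "min2": 2}
    row.update({("nth_min", n): 3 + i for i, n in enumerate(ns)})
    hists = {}
    for kind in kinds:
        k = row[("nth_min", kind.n)] if kind.name == "nth_min" else row[kind.name]
        hists[kind] = DistanceHistogram(
            edges=edges, counts=sums[k], n_trees=config.n_trees, kind=kind,
            sumsq=sumsq[k], nonzero_trees=nonzero[k])
    return EnsembleResult(config=config, edges=edges, histograms=hists,
                          occupancy=occ, occupancy_max=occupancy_max,
                          observed_leaf_counts=leafh, extant_leaf_counts=extanth)
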