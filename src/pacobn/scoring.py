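"""K2 network score, mutual information, and the ant heuristic.

The K2 metric is a Bayesian Dirichlet score for a DAG G over discrete data
D.  Up to a uniform structure prior it factorizes per child node i into

    score(i | Pa_i) = sum_j [ log G(r_i) - log G(N_ij + r_i)
                              + sum_k log G(N_ijk + 1) ]

with r_i the child's cardinality, j running over the parent configurations
realized in the data, N_ijk the number of samples with child level k under
configuration j, and N_ij = sum_k N_ijk.  Unrealized parent configurations
contribute a factor of exactly 1, so summing over realized configurations
only is lossless and far cheaper than the Cartesian product of parent
cardinalities.  Everything is computed in natural-log space through the
log-gamma function; factorials are never formed directly.

The per-child decomposability of the score is what makes arc-by-arc search
cheap: adding arc u -> c changes only child c's term, and that delta —
weighted by (1 + mutual information of the pair) — is the ant heuristic.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.special import gammaln

from .cbn import CBN
from .dataset import DiscreteDataset

__all__ = [
    "LocalScoreCache",
    "K2Scorer",
    "k2_local_score",
    "k2_network_score",
    "mutual_information",
    "mutual_information_table",
    "heuristic",
]

# re-densify running parent-configuration codes before the radix overflows
_REDENSIFY_AT = 2**40


class LocalScoreCache:
    """Map (child, sorted parent tuple) -> log local score, with counters.

    Keys are canonicalized on entry, so a cached value is always the exact
    float a fresh recomputation on the same data would produce.
    """

    def __init__(self):
        self._store: dict[tuple[int, tuple[int, ...]], float] = {}
        self.hits = 0
        self.misses = 0

    @staticmethod
    def key(child: int, parents: Iterable[int]) -> tuple[int, tuple[int, ...]]:
        return (int(child), tuple(sorted(set(map(int, parents)))))

    def get(self, child: int, parents: Iterable[int]) -> float | None:
        val = self._store.get(self.key(child, parents))
        if val is None:
            self.misses += 1
        else:
            self.hits += 1
        return val

    def put(self, child: int, parents: Iterable[int], value: float) -> None:
        self._store[self.key(child, parents)] = value

    def __len__(self) -> int:
        return len(self._store)

    def stats(self) -> dict[str, int]:
        return {"entries": len(self._store), "hits": self.hits, "misses": self.misses}


def _parent_config_ids(levels: np.ndarray, cards: np.ndarray,
                       parents: tuple[int, ...]) -> np.ndarray:
    """Per-sample integer code of the joint parent configuration."""
    m = levels.shape[0]
    ids = np.zeros(m, dtype=np.int64)
    radix = 1
    for p in parents:
        r = int(cards[p])
        if radix * r > _REDENSIFY_AT:
            _, ids = np.unique(ids, return_inverse=True)
            radix = int(ids.max()) + 1
        ids = ids * r + levels[:, p]
        radix *= r
    return ids


def _local_score_from_ids(cfg_ids: np.ndarray, child_levels: np.ndarray,
                          r_child: int, gl: np.ndarray) -> float:
    """Score one child given precomputed parent-configuration codes.

    ``gl`` is a lookup table with gl[n] = log Gamma(n); counts are integers
    bounded by m, so table indexing replaces gammaln calls on the hot path.
    """
    full = cfg_ids * r_child + child_levels
    uniq, counts = np.unique(full, return_counts=True)
    cfg = uniq // r_child
    starts = np.flatnonzero(np.r_[True, cfg[1:] != cfg[:-1]])
    n_ij = np.add.reduceat(counts, starts)
    return float(
        starts.size * gl[r_child]
        - gl[n_ij + r_child].sum()
        + gl[counts + 1].sum()
    )


def _gammaln_table(m: int, r_max: int) -> np.ndarray:
    return gammaln(np.arange(m + r_max + 2, dtype=np.float64))


def k2_local_score(
    child: int,
    parents: Iterable[int],
    data: DiscreteDataset,
    cache: LocalScoreCache | None = None,
) -> float:
    """Log of child's factor of the K2 score (nats), uniform prior dropped."""
    v = data.v
    if not (0 <= child < v):
        raise IndexError(f"child index {child} out of range for {v} nodes")
    parents = tuple(sorted(set(map(int, parents))))
    if child in parents:
        raise ValueError("child must not be among its own parents")
    if parents and (parents[0] < 0 or parents[-1] >= v):
        raise IndexError("parent index out of range")
    if cache is not None:
        hit = cache.get(child, parents)
        if hit is not None:
            return hit
    cards = np.asarray(data.cardinalities, dtype=np.int64)
    gl = _gammaln_table(data.m, int(cards.max()))
    ids = _parent_config_ids(data.levels, cards, parents)
    val = _local_score_from_ids(ids, data.levels[:, child], int(cards[child]), gl)
    if cache is not None:
        cache.put(child, parents, val)
    return val


def k2_network_score(
    graph: CBN,
    data: DiscreteDataset,
    cache: LocalScoreCache | None = None,
) -> float:
    """Sum of per-child local scores: log f(G : D), always <= 0."""
    if graph.v != data.v:
        raise ValueError(
            f"graph has {graph.v} nodes but data has {data.v} columns")
    if not graph.is_acyclic():
        raise ValueError("graph must be acyclic")
    return sum(
        k2_local_score(c, graph.parent_sets[c], data, cache)
        for c in range(graph.v)
    )


def mutual_information(i: int, j: int, data: DiscreteDataset) -> float:
    """Plug-in mutual information between nodes i and j, nats."""
    if i == j:
        raise ValueError("mutual information requires two distinct nodes")
    r_i, r_j = data.cardinalities[i], data.cardinalities[j]
    joint = np.bincount(
        data.levels[:, i] * r_j + data.levels[:, j], minlength=r_i * r_j
    ).reshape(r_i, r_j)
    return _mi_from_contingency(joint)


def _mi_from_contingency(joint: np.ndarray) -> float:
    m = joint.sum()
    p = joint / m
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    mask = p > 0
    terms = p[mask] * np.log(p[mask] / (pi @ pj)[mask])
    # the plug-in estimate is non-negative in exact arithmetic; clip rounding
    return max(float(terms.sum()), 0.0)


def mutual_information_table(data: DiscreteDataset) -> np.ndarray:
    """Symmetric v x v matrix of pairwise mutual information (diagonal 0)."""
    v = data.v
    table = np.zeros((v, v), dtype=np.float64)
    for i in range(v):
        for j in range(i + 1, v):
            table[i, j] = table[j, i] = mutual_information(i, j, data)
    return table


def heuristic(
    parent: int,
    child: int,
    graph: CBN,
    data: DiscreteDataset,
    cache: LocalScoreCache | None = None,
    mi: np.ndarray | None = None,
) -> float:
    """Mutual-information-weighted K2 gain of adding arc parent -> child.

    eta = (1 + Inf(parent, child)) * [score(child | Pa + parent)
                                      - score(child | Pa)]
    The weight is >= 1, so the sign of eta equals the sign of the score
    delta.
    """
    pa = graph.parent_sets[child]
    if parent in pa:
        raise ValueError("arc already present")
    inf = (mutual_information(parent, child, data) if mi is None
           else float(mi[parent, child]))
    delta = (k2_local_score(child, pa | {parent}, data, cache)
             - k2_local_score(child, pa, data, cache))
    return (1.0 + inf) * delta


class K2Scorer:
    """Per-data-set scoring engine with caches for the colony search.

    Bundles the discrete data, a log-gamma lookup table, the precomputed
    mutual-information table, the local-score cache and a cache of
    add-one-parent delta vectors.  The delta cache is the workhorse: one
    entry holds, for a fixed (child, parent set), the score delta of every
    candidate parent at once, so ants retracing common construction
    prefixes pay a dict lookup instead of v local-score evaluations.
    """

    def __init__(self, data: DiscreteDataset):
        self.data = data
        self.levels = np.ascontiguousarray(data.levels, dtype=np.int64)
        self.cards = np.asarray(data.cardinalities, dtype=np.int64)
        self.m, self.v = self.levels.shape
        self.gl = _gammaln_table(self.m, int(self.cards.max()))
        self.cache = LocalScoreCache()
        self.mi = mutual_information_table(data)
        self._cfg_cache: dict[tuple[int, ...], np.ndarray] = {}
        self._delta_cache: dict[tuple[int, tuple[int, ...]], np.ndarray] = {}

    def _configs(self, parents: tuple[int, ...]) -> np.ndarray:
        ids = self._cfg_cache.get(parents)
        if ids is None:
            raw = _parent_config_ids(self.levels, self.cards, parents)
            # densify so downstream radix products stay small
            _, ids = np.unique(raw, return_inverse=True)
            self._cfg_cache[parents] = ids
        return ids

    def local_score(self, child: int, parents: Iterable[int] = ()) -> float:
        parents = tuple(sorted(set(map(int, parents))))
        hit = self.cache.get(child, parents)
        if hit is not None:
            return hit
        val = _local_score_from_ids(
            self._configs(parents), self.levels[:, child],
            int(self.cards[child]), self.gl)
        self.cache.put(child, parents, val)
        return val

    def network_score(self, graph: CBN) -> float:
        if graph.v != self.v:
            raise ValueError("node-count mismatch between graph and data")
        return sum(self.local_score(c, graph.parent_sets[c]) for c in range(self.v))

    def parent_deltas(self, child: int, parents: Iterable[int] = ()) -> np.ndarray:
        """Vector over u of score(child | parents + u) - score(child | parents).

        Entries for u == child or u already a parent are -inf.  The result
        is cached and must not be mutated by callers.
        """
        parents = tuple(sorted(set(map(int, parents))))
        key = (child, parents)
        out = self._delta_cache.get(key)
        if out is not None:
            return out
        base = self.local_score(child, parents)
        ids = self._configs(parents)  # dense, < q <= m
        lev_c = self.levels[:, child]
        r_c = int(self.cards[child])
        out = np.full(self.v, -np.inf)
        skip = set(parents) | {child}
        us = np.array([u for u in range(self.v) if u not in skip], dtype=np.int64)
        if us.size:
            # one segmented count over all candidate parents at once:
            # block codes (config, u-level, child-level) are offset into
            # disjoint integer ranges per u, then counted with one sort
            r_us = self.cards[us]
            q = int(ids.max()) + 1
            big = q * int(r_us.max()) * r_c
            block = (ids[None, :] * r_us[:, None] + self.levels[:, us].T) * r_c
            block += lev_c[None, :]
            block += np.arange(us.size, dtype=np.int64)[:, None] * big
            uniq, counts = np.unique(block.ravel(), return_counts=True)
            u_idx = uniq // big
            grp = uniq // r_c  # distinct per (u, parent configuration)
            starts = np.flatnonzero(np.r_[True, grp[1:] != grp[:-1]])
            n_ij = np.add.reduceat(counts, starts)
            start_u = u_idx[starts]
            n_cfg = np.bincount(start_u, minlength=us.size)
            term_ij = np.bincount(start_u, weights=self.gl[n_ij + r_c],
                                  minlength=us.size)
            term_ijk = np.bincount(u_idx, weights=self.gl[counts + 1],
                                   minlength=us.size)
            scores = n_cfg * self.gl[r_c] - term_ij + term_ijk
            out[us] = scores - base
            # populate the plain cache too so cross-checks are free
            for pos, u in enumerate(us):
                self.cache.put(child, parents + (int(u),), float(scores[pos]))
        self._delta_cache[key] = out
        return out
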