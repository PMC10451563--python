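"""One ant colony: stochastic arc-by-arc DAG construction guided by
pheromone and the K2 heuristic, local search on the iteration best, and
pheromone evaporation/deposit rules.

Ants start from the empty network and repeatedly add one arc, chosen by the
pseudo-random proportional rule of ant colony systems: with probability q0
the ant exploits (takes the arc maximizing tau * eta^beta), otherwise it
explores (samples an arc with probability proportional to tau^alpha *
eta^beta).  Only arcs whose heuristic is strictly positive and whose
addition keeps the graph acyclic are candidates, so the K2 score strictly
increases along a construction and the process terminates when no candidate
remains.  Each selected arc immediately evaporates toward the initial
pheromone tau0 (the local update); after all ants of an iteration finish,
the colony's best-so-far network G+ receives a global deposit proportional
to 1/|f(G+ : D)|.

Note the exponent asymmetry between exploitation (no alpha on tau) and
exploration (tau^alpha): both rules are implemented exactly as stated in
their original forms rather than harmonized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cbn import CBN
from .dataset import DiscreteDataset
from .scoring import K2Scorer

__all__ = [
    "ColonyConfig",
    "ColonyResult",
    "Colony",
    "init_pheromone",
    "candidate_arcs",
    "select_arc",
    "local_pheromone_update",
    "global_pheromone_update",
    "construct_cbn",
    "local_search",
    "run_colony",
]


@dataclass
class ColonyConfig:
    """Tunable parameters of one ant colony.

    Defaults are the settings under which the search is known to be stable:
    alpha=1.2, beta=2, rho=0.35, q0=0.75, 20 ants, 10 iterations.
    """

    alpha: float = 1.2       # pheromone exponent (exploration rule)
    beta: float = 2.0        # heuristic exponent
    rho: float = 0.35        # evaporation rate, in (0, 1]
    q0: float = 0.75         # exploitation probability, in [0, 1)
    tau0: float = 0.1        # initial pheromone, > 0
    num_ants: int = 20       # ants per iteration (Num)
    n_iterations: int = 10   # colony iterations (NC)
    lstep: int = 20          # local-search sweep cap

    def __post_init__(self):
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("rho must be in (0, 1]")
        if not (0.0 <= self.q0 < 1.0):
            raise ValueError("q0 must be in [0, 1)")
        if self.tau0 <= 0.0:
            raise ValueError("tau0 must be positive")
        if self.num_ants < 1 or self.n_iterations < 1:
            raise ValueError("num_ants and n_iterations must be >= 1")
        if self.lstep < 1:
            raise ValueError("lstep must be >= 1")


@dataclass
class ColonyResult:
    """Outcome of one colony's run: best network G+, its score, pheromone."""

    best_graph: CBN
    best_score: float
    pheromone: np.ndarray
    iteration_trace: list[float] = field(default_factory=list)


def init_pheromone(v: int, tau0: float) -> np.ndarray:
    """Uniform v x v pheromone matrix at tau0 (diagonal unused)."""
    return np.full((v, v), float(tau0))


def local_pheromone_update(pheromone: np.ndarray, arc: tuple[int, int],
                           cfg: ColonyConfig) -> None:
    """Evaporate the selected arc toward tau0: tau <- (1-rho) tau + rho tau0."""
    u, c = arc
    pheromone[u, c] = (1.0 - cfg.rho) * pheromone[u, c] + cfg.rho * cfg.tau0


def global_pheromone_update(pheromone: np.ndarray, best_graph: CBN,
                            best_score: float, cfg: ColonyConfig) -> None:
    """Deposit on the arcs of the colony best G+.

    tau <- (1-rho) tau + rho / |f(G+ : D)| on arcs of G+; substituting the
    no-deposit branch (delta = previous tau) leaves every other arc exactly
    unchanged, so it is a no-op here.
    """
    if best_score == 0.0:
        # log K2 of real data is strictly negative; guard the division
        magnitude = np.finfo(float).tiny
    else:
        magnitude = abs(best_score)
    deposit = cfg.rho / magnitude
    for u, c in best_graph.arcs():
        pheromone[u, c] = (1.0 - cfg.rho) * pheromone[u, c] + deposit


def candidate_arcs(graph: CBN, scorer: K2Scorer) -> list[tuple[int, int, float]]:
    """All addable arcs (u, c, eta) with eta > 0 that keep the graph acyclic."""
    eta, mask = _candidate_state(graph, scorer)
    flat = np.flatnonzero(mask)
    return [(int(i) // graph.v, int(i) % graph.v, float(eta.flat[i])) for i in flat]


def _candidate_state(graph: CBN, scorer: K2Scorer):
    """(eta matrix, candidate mask) for an arbitrary graph, from scratch."""
    v = graph.v
    delta = np.empty((v, v))
    for c in range(v):
        delta[:, c] = scorer.parent_deltas(c, graph.parent_sets[c])
    eta = (1.0 + scorer.mi) * delta
    reach = _reachability(graph)
    mask = (eta > 0) & ~reach.T & ~np.eye(v, dtype=bool)
    for c, ps in enumerate(graph.parent_sets):
        for u in ps:
            mask[u, c] = False
    return eta, mask


def _reachability(graph: CBN) -> np.ndarray:
    """Boolean v x v matrix R with R[a, b] = directed path a -> b exists."""
    v = graph.v
    adj = graph.adjacency().astype(bool)
    reach = adj.copy()
    # repeated boolean squaring: O(log v) matmuls
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            return reach
        reach = nxt


def select_arc(
    candidates: Sequence[tuple[int, int, float]],
    pheromone: np.ndarray,
    cfg: ColonyConfig,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Pseudo-random proportional rule over a non-empty candidate set.

    Draw q uniform on [0, 1); exploit (q <= q0) with argmax of
    tau * eta^beta, ties to the smallest (parent, child) pair; otherwise
    sample proportionally to tau^alpha * eta^beta.
    """
    if len(candidates) == 0:
        raise ValueError("select_arc requires a non-empty candidate set")
    cand = sorted(candidates, key=lambda t: (t[0], t[1]))
    us = np.array([t[0] for t in cand])
    cs = np.array([t[1] for t in cand])
    etas = np.array([t[2] for t in cand])
    taus = pheromone[us, cs]
    q = rng.random()
    if q <= cfg.q0:
        # exploitation: tau * eta^beta exactly (no alpha exponent)
        idx = int(np.argmax(taus * etas**cfg.beta))  # first max = lex smallest
    else:
        weights = taus**cfg.alpha * etas**cfg.beta
        total = weights.sum()
        if not np.isfinite(total) or total <= 0:
            idx = int(np.argmax(weights))
        else:
            idx = int(rng.choice(len(cand), p=weights / total))
    return int(us[idx]), int(cs[idx])


def construct_cbn(
    scorer: K2Scorer,
    pheromone: np.ndarray,
    cfg: ColonyConfig,
    rng: np.random.Generator,
) -> tuple[CBN, float]:
    """One ant's construction: empty network, add arcs until no candidate.

    Applies the local pheromone update after every selection.  Returns the
    network and its K2 score (recomputed exactly at the end).
    """
    v = scorer.v
    graph = CBN(v, node_labels=scorer.data.node_labels)
    parents: list[tuple[int, ...]] = [() for _ in range(v)]
    delta = np.empty((v, v))
    for c in range(v):
        delta[:, c] = scorer.parent_deltas(c, ())
    eta = (1.0 + scorer.mi) * delta
    reach = np.zeros((v, v), dtype=bool)
    present = np.zeros((v, v), dtype=bool)
    diag = np.eye(v, dtype=bool)
    node_idx = np.arange(v)

    while True:
        mask = (eta > 0) & ~present & ~reach.T & ~diag
        flat = np.flatnonzero(mask)
        if flat.size == 0:
            break
        u, c = _select_from_arrays(flat, eta, pheromone, cfg, rng, v)
        graph.add_arc(u, c)
        present[u, c] = True
        parents[c] = tuple(sorted(parents[c] + (u,)))
        col = scorer.parent_deltas(c, parents[c])
        delta[:, c] = col
        eta[:, c] = (1.0 + scorer.mi[:, c]) * col
        # transitive-closure update: everything reaching u now reaches
        # everything reachable from c
        anc = reach[:, u] | (node_idx == u)
        desc = reach[c, :] | (node_idx == c)
        reach |= anc[:, None] & desc[None, :]
        local_pheromone_update(pheromone, (u, c), cfg)

    return graph, scorer.network_score(graph)


def _select_from_arrays(flat, eta, pheromone, cfg, rng, v):
    """Vectorized pseudo-random proportional rule on flat candidate indices.

    ``flat`` is sorted (row-major), so the first argmax is the smallest
    (parent, child) pair — the deterministic tie-break.
    """
    etas = eta.flat[flat]
    taus = pheromone.flat[flat]
    q = rng.random()
    if q <= cfg.q0:
        idx = int(np.argmax(taus * etas**cfg.beta))
    else:
        weights = taus**cfg.alpha * etas**cfg.beta
        total = weights.sum()
        if not np.isfinite(total) or total <= 0:
            idx = int(np.argmax(weights))
        else:
            idx = int(rng.choice(flat.size, p=weights / total))
    j = int(flat[idx])
    return j // v, j % v


def local_search(graph: CBN, scorer: K2Scorer, cfg: ColonyConfig) -> tuple[CBN, float]:
    """First-improvement hill climbing with add / delete / reverse moves.

    Sweeps all single-arc moves in a fixed order, applying each improving
    move immediately; stops after a sweep with no improvement or after
    ``cfg.lstep`` sweeps.  The result is acyclic and scores at least as
    high as the input.
    """
    g = graph.copy()
    v = g.v
    for _ in range(cfg.lstep):
        improved = False
        reach = _reachability_sets(g)

        # additions (re-scan the child after every applied move: the
        # remaining deltas change with its parent set)
        for c in range(v):
            while True:
                deltas = scorer.parent_deltas(c, g.parent_sets[c])
                applied = False
                for u in np.flatnonzero(deltas > 0):
                    u = int(u)
                    if u in reach[c]:  # path c -> u exists; u -> c cycles
                        continue
                    g.add_arc(u, c)
                    reach = _reachability_sets(g)
                    improved = applied = True
                    break
                if not applied:
                    break

        # deletions
        for u, c in g.arcs():
            base = scorer.local_score(c, g.parent_sets[c])
            without = scorer.local_score(c, g.parent_sets[c] - {u})
            if without - base > 0:
                g.remove_arc(u, c)
                reach = _reachability_sets(g)
                improved = True

        # reversals: u -> c becomes c -> u
        for u, c in g.arcs():
            pa_c = g.parent_sets[c]
            pa_u = g.parent_sets[u]
            d = (scorer.local_score(c, pa_c - {u}) - scorer.local_score(c, pa_c)
                 + scorer.local_score(u, pa_u | {c}) - scorer.local_score(u, pa_u))
            if d <= 0:
                continue
            g.remove_arc(u, c)
            if g.has_path(u, c):  # another u ~> c path: reversal would cycle
                g.add_arc(u, c)
                continue
            g.add_arc(c, u)
            reach = _reachability_sets(g)
            improved = True

        if not improved:
            break
    return g, scorer.network_score(g)


def _reachability_sets(graph: CBN) -> list[set[int]]:
    """reach[a] = set of nodes with a directed path from a."""
    v = graph.v
    children: list[list[int]] = [[] for _ in range(v)]
    for c, ps in enumerate(graph.parent_sets):
        for u in ps:
            children[u].append(c)
    reach: list[set[int]] = [set() for _ in range(v)]
    for order_node in (graph.topological_order() or [])[::-1]:
        acc: set[int] = set()
        for ch in children[order_node]:
            acc.add(ch)
            acc |= reach[ch]
        reach[order_node] = acc
    return reach


class Colony:
    """Mutable search state of one colony bound to one data set."""

    def __init__(self, data: DiscreteDataset, cfg: ColonyConfig,
                 colony_index: int = 0, base_seed: int = 0):
        self.scorer = K2Scorer(data)
        self.cfg = cfg
        self.index = int(colony_index)
        self.base_seed = int(base_seed)
        if self.base_seed < 0 or self.index < 0:
            raise ValueError("seeds and colony indices must be non-negative")
        self.pheromone = init_pheromone(self.scorer.v, cfg.tau0)
        self.best_graph: CBN | None = None
        self.best_score = -np.inf
        self.iteration_trace: list[float] = []

    def _ant_rng(self, iteration: int, ant: int) -> np.random.Generator:
        # stream depends only on identity, never on execution order
        return np.random.default_rng(
            [self.base_seed, self.index, iteration, ant])

    def run_iteration(self, iteration: int) -> None:
        """Num ant constructions, local search on the iteration best,
        colony-best bookkeeping, then the global pheromone update."""
        it_best: CBN | None = None
        it_score = -np.inf
        for ant in range(self.cfg.num_ants):
            rng = self._ant_rng(iteration, ant)
            g, s = construct_cbn(self.scorer, self.pheromone, self.cfg, rng)
            if s > it_score:
                it_best, it_score = g, s
        assert it_best is not None
        refined, refined_score = local_search(it_best, self.scorer, self.cfg)
        if refined_score > self.best_score:
            self.best_graph, self.best_score = refined, refined_score
        assert self.best_graph is not None
        global_pheromone_update(self.pheromone, self.best_graph,
                                self.best_score, self.cfg)
        self.iteration_trace.append(self.best_score)

    def result(self) -> ColonyResult:
        if self.best_graph is None:
            raise RuntimeError("colony has not run any iteration")
        return ColonyResult(self.best_graph.copy(), float(self.best_score),
                            self.pheromone.copy(), list(self.iteration_trace))


def run_colony(data: DiscreteDataset, cfg: ColonyConfig | None = None,
               seed: int = 0) -> ColonyResult:
    """Run one standalone colony for its configured number of iterations.

    This is the single-data-set reduction of the parallel algorithm (the
    classic ant colony system over one signal table).
    """
    cfg = cfg or ColonyConfig()
    colony = Colony(data, cfg, colony_index=0, base_seed=seed)
    for t in range(cfg.n_iterations):
        colony.run_iteration(t)
    return colony.result()
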