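"""Parallel multi-colony search with pheromone fusion and consensus fusion.

One colony runs per input data set.  After every iteration the colonies
synchronize at a barrier: the pheromone matrix of the colony whose
best-so-far network scores highest (Mmax) overwrites every colony's matrix,
so all colonies restart the next iteration from the globally most promising
trail.  After the final iteration the N colony-best networks are fused by
majority vote — an arc enters the final network G' iff at least half the
colonies learned it — and G' is repaired to a DAG if the vote produced
orientation conflicts or cycles.

Determinism: every ant's random stream is derived from
(base_seed, colony index, iteration, ant index), so serial and threaded
execution produce bit-identical results.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cbn import CBN
from .colony import Colony, ColonyConfig, ColonyResult
from .dataset import (DiscreteDataset, DiscretizerSpec, SignalDataset,
                      discretize)

__all__ = [
    "PacoConfig",
    "ConsensusResult",
    "fuse_pheromones",
    "fuse_cbns",
    "run_paco",
]


@dataclass
class PacoConfig:
    """Run-level configuration: one colony per data set plus fusion rules."""

    colony: ColonyConfig = field(default_factory=ColonyConfig)
    consensus_fraction: float = 0.5
    base_seed: int = 0
    max_workers: int = 1
    fusion_every: int = 1  # barrier frequency in iterations

    def __post_init__(self):
        if not (0.0 < self.consensus_fraction <= 1.0):
            raise ValueError("consensus_fraction must be in (0, 1]")
        if self.base_seed < 0:
            raise ValueError("base_seed must be non-negative")
        if self.max_workers < 1:
            raise ValueError("max_workers must be >= 1")
        if self.fusion_every < 1:
            raise ValueError("fusion_every must be >= 1")


@dataclass
class ConsensusResult:
    """Arc-vote matrix over colony-best networks and the extracted G'."""

    count_matrix: np.ndarray
    final_graph: CBN
    per_colony: list[ColonyResult] = field(default_factory=list)
    winner_trace: list[tuple[int, int, float]] = field(default_factory=list)
    # winner_trace rows: (iteration, winning colony index, its best score)


def fuse_pheromones(
    results: Sequence[tuple[np.ndarray, float]],
) -> np.ndarray:
    """Return a copy of the pheromone matrix of the best-scoring colony.

    Ties go to the lowest colony index.  Callers broadcast the returned
    matrix to every colony.
    """
    if len(results) == 0:
        raise ValueError("fuse_pheromones requires at least one colony")
    shapes = {np.asarray(p).shape for p, _ in results}
    if len(shapes) != 1:
        raise ValueError(f"pheromone shape mismatch across colonies: {shapes}")
    best = max(range(len(results)), key=lambda i: (results[i][1], -i))
    return np.array(results[best][0], copy=True)


def fuse_cbns(graphs: Sequence[CBN], consensus_fraction: float = 0.5) -> ConsensusResult:
    """Majority-vote fusion of colony-best networks into the final G'.

    count_matrix[u, c] counts graphs containing arc u -> c; an arc is kept
    iff its count >= consensus_fraction * N (exactly half passes).  If both
    orientations of a pair pass, only the larger count survives (tie:
    neither).  Any residual directed cycle is broken by removing arcs in
    ascending count order.
    """
    if len(graphs) == 0:
        raise ValueError("fuse_cbns requires at least one graph")
    v = graphs[0].v
    labels = graphs[0].node_labels
    for g in graphs:
        if g.v != v or g.node_labels != labels:
            raise ValueError("all graphs must share the same node set")
    counts = np.zeros((v, v), dtype=np.int64)
    for g in graphs:
        counts += g.adjacency()
    n = len(graphs)
    threshold = consensus_fraction * n
    keep = counts.astype(float) >= threshold - 1e-12

    final = CBN(v, node_labels=labels)
    for u in range(v):
        for c in range(u + 1, v):
            fwd, rev = keep[u, c], keep[c, u]
            if fwd and rev:
                if counts[u, c] > counts[c, u]:
                    final.add_arc(u, c)
                elif counts[c, u] > counts[u, c]:
                    final.add_arc(c, u)
                # exact tie: keep neither orientation
            elif fwd:
                final.add_arc(u, c)
            elif rev:
                final.add_arc(c, u)

    _break_cycles(final, counts)
    return ConsensusResult(count_matrix=counts, final_graph=final)


def _break_cycles(graph: CBN, counts: np.ndarray) -> None:
    """Greedily drop lowest-vote arcs (ties by index) until acyclic."""
    order = sorted(graph.arcs(), key=lambda a: (counts[a[0], a[1]], a[0], a[1]))
    for u, c in order:
        if graph.is_acyclic():
            return
        # the arc sits on a directed cycle iff a return path c ~> u exists
        graph.remove_arc(u, c)
        if not graph.has_path(c, u):
            graph.add_arc(u, c)


def _reconcile_labels(datasets: Sequence[DiscreteDataset]) -> list[DiscreteDataset]:
    """Reorder every data set's columns to the first data set's label order."""
    ref = datasets[0].node_labels
    out = [datasets[0]]
    for d in datasets[1:]:
        if d.node_labels == ref:
            out.append(d)
            continue
        if sorted(d.node_labels) != sorted(ref):
            raise ValueError(
                "data sets must share node labels; got "
                f"{ref} vs {d.node_labels}")
        idx = [d.node_labels.index(lbl) for lbl in ref]
        out.append(DiscreteDataset(d.levels[:, idx],
                                   [d.cardinalities[i] for i in idx],
                                   list(ref)))
    return out


def run_paco(
    datasets: Sequence[SignalDataset | DiscreteDataset],
    cfg: PacoConfig | None = None,
    discretizer: DiscretizerSpec | None = None,
) -> ConsensusResult:
    """Learn one consensus network from N data sets with N colonies.

    Continuous inputs are discretized per colony; discrete inputs are used
    as-is.  With N = 1 this reduces to a single classic ant colony.
    """
    cfg = cfg or PacoConfig()
    if len(datasets) == 0:
        raise ValueError("run_paco requires at least one data set")
    discrete = [
        d if isinstance(d, DiscreteDataset) else discretize(d, discretizer)
        for d in datasets
    ]
    discrete = _reconcile_labels(discrete)

    colonies = [
        Colony(d, cfg.colony, colony_index=i, base_seed=cfg.base_seed)
        for i, d in enumerate(discrete)
    ]
    winner_trace: list[tuple[int, int, float]] = []

    for t in range(cfg.colony.n_iterations):
        if cfg.max_workers > 1 and len(colonies) > 1:
            with ThreadPoolExecutor(max_workers=cfg.max_workers) as pool:
                list(pool.map(lambda col: col.run_iteration(t), colonies))
        else:
            for col in colonies:
                col.run_iteration(t)
        if (t + 1) % cfg.fusion_every == 0 or t == cfg.colony.n_iterations - 1:
            fused = fuse_pheromones(
                [(col.pheromone, col.best_score) for col in colonies])
            winner = max(range(len(colonies)),
                         key=lambda i: (colonies[i].best_score, -i))
            winner_trace.append((t, winner, float(colonies[winner].best_score)))
            for col in colonies:
                col.pheromone = fused.copy()

    results = [col.result() for col in colonies]
    consensus = fuse_cbns([r.best_graph for r in results],
                          cfg.consensus_fraction)
    consensus.per_colony = results
    consensus.winner_trace = winner_trace
    return consensus
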