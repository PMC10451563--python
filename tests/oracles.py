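"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: pure-Python nested loops, explicit
Cartesian products over parent configurations, and exhaustive DAG
enumeration.  None of it shares code with the package internals.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from pacobn.cbn import CBN


def naive_k2_local(levels, cards, child, parents) -> float:
    """Direct evaluation of the child's log K2 factor by nested loops."""
    levels = np.asarray(levels)
    m = levels.shape[0]
    r = cards[child]
    parents = list(parents)
    total = 0.0
    for combo in product(*[range(cards[p]) for p in parents]):
        counts = [0] * r
        for s in range(m):
            if all(levels[s, p] == val for p, val in zip(parents, combo)):
                counts[levels[s, child]] += 1
        n_ij = sum(counts)
        total += (math.lgamma(r) - math.lgamma(n_ij + r)
                  + sum(math.lgamma(c + 1) for c in counts))
    return total


def naive_k2_network(levels, cards, graph: CBN) -> float:
    return sum(
        naive_k2_local(levels, cards, c, sorted(graph.parent_sets[c]))
        for c in range(graph.v)
    )


def naive_mutual_information(levels, cards, i, j) -> float:
    """Plug-in MI from an explicitly built contingency table."""
    levels = np.asarray(levels)
    m = levels.shape[0]
    table = [[0] * cards[j] for _ in range(cards[i])]
    for s in range(m):
        table[levels[s, i]][levels[s, j]] += 1
    mi = 0.0
    for a in range(cards[i]):
        for b in range(cards[j]):
            n_ab = table[a][b]
            if n_ab == 0:
                continue
            n_a = sum(table[a])
            n_b = sum(row[b] for row in table)
            mi += (n_ab / m) * math.log(n_ab * m / (n_a * n_b))
    return mi


def all_dags(v: int):
    """Every DAG over v labelled nodes, by filtering all digraphs.

    Feasible for v <= 4 (4096 digraphs, 543 DAGs).
    """
    pairs = [(u, c) for u in range(v) for c in range(v) if u != c]
    dags = []
    for bits in range(1 << len(pairs)):
        edges = [pairs[k] for k in range(len(pairs)) if bits >> k & 1]
        g = CBN.from_edges(edges, v)
        if g.is_acyclic():
            dags.append(g)
    return dags


def best_dag_by_enumeration(levels, cards, score_fn):
    """Exhaustively score every DAG; returns (best graph, best score).

    ``score_fn(graph)`` supplies the scoring route under test, so the
    enumeration (the oracle part) stays independent of how scores are
    computed.
    """
    v = len(cards)
    best, best_score = None, -math.inf
    for g in all_dags(v):
        s = score_fn(g)
        if s > best_score:
            best, best_score = g, s
    return best, best_score
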