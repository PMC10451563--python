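"""Causal biological network (CBN): a DAG stored as per-node parent sets.

A CBN over ``v`` nodes holds one arc ``u -> c`` per causal influence of node
``u`` (parent) on node ``c`` (child).  Acyclicity is the only structural
constraint; the class offers the incremental mutators the search needs plus
topological-sort based acyclicity checks used by invariant assertions.
"""

from __future__ import annotations

from collections import deque
from collections.abc import Iterable, Sequence

import numpy as np

__all__ = ["CBN"]


def default_labels(v: int) -> list[str]:
    return [f"X{i + 1}" for i in range(v)]


class CBN:
    """Directed acyclic graph over labelled nodes, arcs as parent sets."""

    __slots__ = ("v", "parent_sets", "node_labels")

    def __init__(
        self,
        v: int,
        parent_sets: Sequence[Iterable[int]] | None = None,
        node_labels: Sequence[str] | None = None,
    ):
        if v < 1:
            raise ValueError("a CBN needs at least one node")
        self.v = int(v)
        if parent_sets is None:
            self.parent_sets: list[set[int]] = [set() for _ in range(v)]
        else:
            if len(parent_sets) != v:
                raise ValueError("parent_sets length must equal node count")
            self.parent_sets = [set(map(int, ps)) for ps in parent_sets]
            for c, ps in enumerate(self.parent_sets):
                if c in ps:
                    raise ValueError(f"self-arc on node {c}")
                if ps and (min(ps) < 0 or max(ps) >= v):
                    raise ValueError(f"parent index out of range for node {c}")
        if node_labels is None:
            node_labels = default_labels(v)
        if len(node_labels) != v:
            raise ValueError("node_labels length must equal node count")
        self.node_labels = list(node_labels)

    # -- queries ---------------------------------------------------------

    def parents(self, c: int) -> frozenset[int]:
        return frozenset(self.parent_sets[c])

    def has_arc(self, u: int, c: int) -> bool:
        return u in self.parent_sets[c]

    def arcs(self) -> list[tuple[int, int]]:
        """All arcs (parent, child), sorted lexicographically."""
        return sorted((u, c) for c, ps in enumerate(self.parent_sets) for u in ps)

    @property
    def n_arcs(self) -> int:
        return sum(len(ps) for ps in self.parent_sets)

    def adjacency(self) -> np.ndarray:
        """Binary v x v matrix with A[u, c] = 1 iff arc u -> c."""
        a = np.zeros((self.v, self.v), dtype=np.int8)
        for c, ps in enumerate(self.parent_sets):
            for u in ps:
                a[u, c] = 1
        return a

    def topological_order(self) -> list[int] | None:
        """Kahn's algorithm; None if the graph contains a directed cycle."""
        indeg = [len(ps) for ps in self.parent_sets]
        children: list[list[int]] = [[] for _ in range(self.v)]
        for c, ps in enumerate(self.parent_sets):
            for u in ps:
                children[u].append(c)
        queue = deque(i for i, d in enumerate(indeg) if d == 0)
        order: list[int] = []
        while queue:
            u = queue.popleft()
            order.append(u)
            for c in children[u]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return order if len(order) == self.v else None

    def is_acyclic(self) -> bool:
        return self.topological_order() is not None

    def has_path(self, src: int, dst: int) -> bool:
        """True iff a directed path src -> ... -> dst exists (src != dst)."""
        children: list[list[int]] = [[] for _ in range(self.v)]
        for c, ps in enumerate(self.parent_sets):
            for u in ps:
                children[u].append(c)
        seen = {src}
        stack = [src]
        while stack:
            node = stack.pop()
            for c in children[node]:
                if c == dst:
                    return True
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    # -- mutators --------------------------------------------------------

    def add_arc(self, u: int, c: int) -> None:
        if u == c:
            raise ValueError("self-arcs are not allowed")
        if not (0 <= u < self.v and 0 <= c < self.v):
            raise IndexError("arc endpoint out of range")
        self.parent_sets[c].add(u)

    def remove_arc(self, u: int, c: int) -> None:
        self.parent_sets[c].discard(u)

    def copy(self) -> "CBN":
        return CBN(self.v, [set(ps) for ps in self.parent_sets], self.node_labels)

    # -- constructors / dunder -------------------------------------------

    @classmethod
    def from_adjacency(cls, adjacency: np.ndarray, node_labels=None) -> "CBN":
        a = np.asarray(adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        v = a.shape[0]
        parent_sets = [set(np.flatnonzero(a[:, c]).tolist()) for c in range(v)]
        return cls(v, parent_sets, node_labels)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[int, int]], v: int, node_labels=None) -> "CBN":
        g = cls(v, node_labels=node_labels)
        for u, c in edges:
            g.add_arc(u, c)
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, CBN):
            return NotImplemented
        return self.v == other.v and self.parent_sets == other.parent_sets

    def __hash__(self):  # pragma: no cover - CBNs are mutable, not hashed
        raise TypeError("CBN is mutable and unhashable")

    def __repr__(self) -> str:
        return f"CBN(v={self.v}, arcs={self.n_arcs})"
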