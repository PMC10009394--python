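"""Two-slice dynamic Bayesian network structures.

A first-order stationary DBN over ``n`` binary variables is described by a
pair of adjacency matrices:

* ``within`` (``W``): the directed acyclic graph connecting variables
  *inside* a time-slice; assumed identical in every slice.
* ``between`` (``B``): directed edges from variables at slice ``t`` to
  variables at slice ``t + 1``.  ``B[i, j]`` means ``i`` at time ``t``
  is a parent of ``j`` at time ``t + 1``.  Because time orients these
  edges, ``B`` is unconstrained (self-edges ``i -> i`` are allowed and
  encode a symptom's "momentum").

Unrolling two slices gives a ``2n``-node DAG: slice-1 nodes ``0..n-1``,
slice-2 nodes ``n..2n-1``.  Edges from slice 2 back to slice 1 can never
be represented, which is the time-ordering blacklist.
"""

from __future__ import annotations

import numpy as np
import networkx as nx


class StructureError(ValueError):
    """An adjacency pair violates the DBN constraints."""


def topological_order(adj: np.ndarray) -> list[int] | None:
    """Kahn topological sort of a boolean adjacency matrix.

    Returns a node order with parents before children, or ``None`` if the
    graph contains a cycle.
    """
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    indeg = adj.sum(axis=0).astype(int)
    stack = [v for v in range(n) if indeg[v] == 0]
    order: list[int] = []
    while stack:
        v = stack.pop()
        order.append(v)
        for w in np.flatnonzero(adj[v]):
            indeg[w] -= 1
            if indeg[w] == 0:
                stack.append(int(w))
    return order if len(order) == n else None


class DbnStructure:
    """Immutable pair (within-slice DAG, between-slice matrix)."""

    __slots__ = ("within", "between", "n", "_key")

    def __init__(self, within, between):
        W = np.ascontiguousarray(np.asarray(within, dtype=bool))
        B = np.ascontiguousarray(np.asarray(between, dtype=bool))
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise StructureError("within-slice adjacency must be square")
        if B.shape != W.shape:
            raise StructureError("between-slice adjacency shape mismatch")
        if W.diagonal().any():
            raise StructureError("within-slice self-loops are not allowed")
        if topological_order(W) is None:
            raise StructureError("within-slice graph contains a cycle")
        W.setflags(write=False)
        B.setflags(write=False)
        self.within = W
        self.between = B
        self.n = W.shape[0]
        self._key = (W.tobytes(), B.tobytes(), self.n)

    # -- parent accessors -------------------------------------------------
    def w_parents(self, j: int) -> np.ndarray:
        """Within-slice parents of node ``j`` (sorted indices)."""
        return np.flatnonzero(self.within[:, j])

    def b_parents(self, j: int) -> np.ndarray:
        """Slice-1 parents of slice-2 node ``j`` (sorted indices)."""
        return np.flatnonzero(self.between[:, j])

    def n_edges(self) -> int:
        return int(self.within.sum() + self.between.sum())

    def unrolled(self) -> nx.DiGraph:
        """Unroll to the explicit 2n-node transition DAG.

        Acyclicity of the unrolled graph is automatic when ``within`` is
        acyclic, but we assert it anyway.
        """
        n = self.n
        g = nx.DiGraph()
        g.add_nodes_from(range(2 * n))
        for i, j in zip(*np.nonzero(self.within)):
            g.add_edge(int(i), int(j))
            g.add_edge(int(i) + n, int(j) + n)
        for i, j in zip(*np.nonzero(self.between)):
            g.add_edge(int(i), int(j) + n)
        if not nx.is_directed_acyclic_graph(g):  # pragma: no cover
            raise StructureError("unrolled transition graph is cyclic")
        return g

    # -- hashing / equality ----------------------------------------------
    def __eq__(self, other):
        return isinstance(other, DbnStructure) and self._key == other._key

    def __hash__(self):
        return hash(self._key)

    def __repr__(self):
        return (f"DbnStructure(n={self.n}, within_edges={int(self.within.sum())}, "
                f"between_edges={int(self.between.sum())})")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "within": [[int(i), int(j)] for i, j in zip(*np.nonzero(self.within))],
            "between": [[int(i), int(j)] for i, j in zip(*np.nonzero(self.between))],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DbnStructure":
        n = int(d["n"])
        W = np.zeros((n, n), dtype=bool)
        B = np.zeros((n, n), dtype=bool)
        for i, j in d["within"]:
            W[i, j] = True
        for i, j in d["between"]:
            B[i, j] = True
        return cls(W, B)

    @classmethod
    def empty(cls, n: int) -> "DbnStructure":
        return cls(np.zeros((n, n), dtype=bool), np.zeros((n, n), dtype=bool))
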