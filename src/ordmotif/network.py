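"""Directed networks with a strict total order on their nodes."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Node = Hashable
Edge = tuple[Node, Node]


@dataclass(frozen=True)
class OrderedNetwork:
    """A directed graph whose nodes form a totally ordered set.

    Edges follow the energy-flow convention of food webs: an edge from
    A to B means B eats A, so "upward" links run from low rank (small
    prey) to high rank (large predator) when rank follows body mass.

    Parameters
    ----------
    nodes
        Node identifiers in ascending rank order (rank of ``nodes[i]``
        is ``i + 1``).
    edges
        Directed edges as (source, target) pairs.  Self-loops
        (cannibalism) may be stored; they never enter 3-node counts.
    niche_value
        Optional niche variable per node (e.g. adult body mass); when
        built via :meth:`from_niche_values` the rank order ascends in it.
    """

    nodes: tuple[Node, ...]
    edges: frozenset[Edge]
    niche_value: Mapping[Node, float] | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint {u if u not in node_set else v!r} is not a node")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Edge],
        nodes: Sequence[Node] | None = None,
        niche_value: Mapping[Node, float] | None = None,
    ) -> "OrderedNetwork":
        """Build a network, ordering nodes by niche value if given.

        Without niche values the rank order is the order of ``nodes``
        (or of first appearance in the edge list).  Ties in the niche
        value are broken by input order, with a warning, since the
        order must be strict.
        """
        edges = list(edges)
        if nodes is None:
            seen: dict[Node, None] = {}
            for u, v in edges:
                seen.setdefault(u)
                seen.setdefault(v)
            nodes = list(seen)
        else:
            nodes = list(nodes)
        if niche_value is not None:
            missing = [n for n in nodes if n not in niche_value]
            if missing:
                raise ValueError(f"no niche value for node(s) {missing[:5]!r}")
            values = [niche_value[n] for n in nodes]
            if len(set(values)) < len(values):
                warnings.warn(
                    "ties in niche values; rank order among tied nodes follows "
                    "input order",
                    stacklevel=2,
                )
            order = sorted(range(len(nodes)), key=lambda i: (values[i], i))
            nodes = [nodes[i] for i in order]
        return cls(tuple(nodes), frozenset(edges), niche_value)

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_self_loops(self) -> int:
        return sum(1 for u, v in self.edges if u == v)

    @property
    def connectance(self) -> float:
        """Directed connectance C = L / N**2 (self-loops included in L)."""
        return self.n_edges / self.n**2

    def rank(self, node: Node) -> int:
        """Rank 1..N of a node (1 = lowest)."""
        return self.nodes.index(node) + 1

    def adjacency(self) -> np.ndarray:
        """Boolean adjacency matrix in rank order.

        ``A[i, j]`` is True iff there is an edge from the node of rank
        i+1 to the node of rank j+1.
        """
        index = {node: i for i, node in enumerate(self.nodes)}
        a = np.zeros((self.n, self.n), dtype=bool)
        for u, v in self.edges:
            a[index[u], index[v]] = True
        return a

    # -- order manipulations ---------------------------------------------

    def with_order(self, nodes_in_rank_order: Sequence[Node]) -> "OrderedNetwork":
        """Same topology under a different total order."""
        if set(nodes_in_rank_order) != set(self.nodes):
            raise ValueError("new order must contain exactly the same nodes")
        return OrderedNetwork(tuple(nodes_in_rank_order), self.edges, self.niche_value)

    def reversed_order(self) -> "OrderedNetwork":
        """The top-down mirror: rank -> N + 1 - rank."""
        return self.with_order(tuple(reversed(self.nodes)))

    def shuffled_order(self, rng: np.random.Generator) -> "OrderedNetwork":
        """Uniformly random rank assignment, topology fixed."""
        perm = rng.permutation(self.n)
        return self.with_order(tuple(self.nodes[i] for i in perm))
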