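"""Catalog of ordered 3-node substructures.

In a directed network whose nodes carry a strict total order ("rank"),
any pair of distinct nodes is in one of four states: unconnected, linked
downward (higher rank -> lower rank), linked upward, or linked in both
directions.  A triple of rank-ordered nodes therefore realises one of
4**3 = 64 configurations.  Ten of these leave at least one node without
any incident link; the remaining 54 *connected ordered substructures*
form the catalog built here.

Ignoring the node order collapses the 54 substructures onto the 13
classical connected 3-node digraph classes of standard motif analysis.
Each substructure is labelled (q, s): q is the isomorphism class
(1..13) and s the member within the class (1..6).  The numbering is a
deterministic convention of this package (classes sorted by link count,
then by canonical edge set; members in lexicographic code order); the
three substructures that matter most in upward-biased networks are also
reachable through structural aliases:

``fan_in_up``
    both lower nodes link upward into the top node (a predator feeding
    on two smaller prey),
``up_chain``
    bottom -> middle -> top (a body-size-ordered tri-trophic chain),
``fan_out_up``
    the bottom node links upward to both others (a prey shared by two
    larger predators).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from functools import lru_cache
from itertools import permutations, product
from typing import Iterator

import pandas as pd

SCHEMA_VERSION = "1"

#: Node-pair slots of a rank-ordered triple, as (lower, higher) rank
#: positions with 0 = bottom, 1 = middle, 2 = top.  The slot order
#: (bottom,middle), (bottom,top), (middle,top) is fixed package-wide.
PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (1, 2))

N_CODES = 64
N_CONNECTED = 54
N_CLASSES = 13


class PairState(IntEnum):
    """Relation between two rank-ordered nodes (lower, higher)."""

    NONE = 0   #: no link
    DOWN = 1   #: single link higher -> lower rank
    UP = 2     #: single link lower -> higher rank
    BIDIR = 3  #: links in both directions


#: A substructure code: pair states for the slots in :data:`PAIRS`.
Code = tuple[PairState, PairState, PairState]


def enumerate_codes() -> list[Code]:
    """All 64 ordered 3-node configuration codes, in a fixed order."""
    return [tuple(states) for states in product(PairState, repeat=3)]


def code_index(code: Code) -> int:
    """Dense index 0..63 of a code (base-4 positional encoding)."""
    return 16 * int(code[0]) + 4 * int(code[1]) + int(code[2])


def code_edges(code: Code) -> frozenset[tuple[int, int]]:
    """Directed edges of a code's digraph on rank positions {0,1,2}."""
    edges = set()
    for (lo, hi), state in zip(PAIRS, code):
        if state in (PairState.UP, PairState.BIDIR):
            edges.add((lo, hi))
        if state in (PairState.DOWN, PairState.BIDIR):
            edges.add((hi, lo))
    return frozenset(edges)


def edges_to_code(edges: frozenset[tuple[int, int]]) -> Code:
    """Inverse of :func:`code_edges` for edges on {0,1,2}."""
    states = []
    for lo, hi in PAIRS:
        up = (lo, hi) in edges
        down = (hi, lo) in edges
        states.append(PairState(2 * up + down))
    return tuple(states)


def is_connected_substructure(code: Code) -> bool:
    """True iff every node of the triple has at least one incident link.

    With only three nodes this coincides with weak connectivity: a
    configuration without isolated nodes cannot split into components.
    """
    edges = code_edges(code)
    touched = {v for e in edges for v in e}
    return len(touched) == 3


def _canonical_edges(edges: frozenset[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    # Minimum over the 6 relabellings of {0,1,2}: an exact canonical form
    # for 3-node digraph isomorphism.
    return min(
        tuple(sorted((p[a], p[b]) for a, b in edges))
        for p in permutations(range(3))
    )


def automorphism_count(edges: frozenset[tuple[int, int]]) -> int:
    """Order of the automorphism group of a 3-node digraph."""
    return sum(
        1
        for p in permutations(range(3))
        if frozenset((p[a], p[b]) for a, b in edges) == edges
    )


@dataclass(frozen=True)
class CatalogEntry:
    """One connected ordered substructure."""

    code: Code
    class_id: int    #: isomorphism class q, 1..13
    member_id: int   #: member s within the class, 1..6
    link_count: int  #: directed links l, 2..6 (BIDIR contributes 2)
    up_count: int
    down_count: int

    @property
    def key(self) -> tuple[int, int]:
        return (self.class_id, self.member_id)

    @property
    def label(self) -> str:
        return f"({self.class_id},{self.member_id})"

    def code_str(self) -> str:
        return "|".join(s.name for s in self.code)


def _link_counts(code: Code) -> tuple[int, int]:
    up = sum(1 for s in code if s in (PairState.UP, PairState.BIDIR))
    down = sum(1 for s in code if s in (PairState.DOWN, PairState.BIDIR))
    return up, down


class Catalog:
    """The 54 connected ordered substructures and their class structure.

    Iterating yields :class:`CatalogEntry` objects in (q, s) order, the
    canonical spectrum order used by every counting routine.
    """

    def __init__(self) -> None:
        connected = [c for c in enumerate_codes() if is_connected_substructure(c)]
        groups: dict[tuple, list[Code]] = {}
        for code in connected:
            groups.setdefault(_canonical_edges(code_edges(code)), []).append(code)
        # class order: by link count, then canonical edge set; member
        # order: lexicographic on the code tuple.  Deterministic on any
        # platform.
        def class_key(item):
            canon, members = item
            return (len(code_edges(members[0])), canon)

        entries: list[CatalogEntry] = []
        self.class_index: dict[tuple, int] = {}
        for q, (canon, members) in enumerate(sorted(groups.items(), key=class_key), start=1):
            self.class_index[canon] = q
            for s, code in enumerate(sorted(members, key=lambda c: tuple(map(int, c))), start=1):
                up, down = _link_counts(code)
                entries.append(
                    CatalogEntry(
                        code=code,
                        class_id=q,
                        member_id=s,
                        link_count=up + down,
                        up_count=up,
                        down_count=down,
                    )
                )
        self.entries: list[CatalogEntry] = entries
        self._by_code: dict[Code, CatalogEntry] = {e.code: e for e in entries}
        self._by_key: dict[tuple[int, int], CatalogEntry] = {e.key: e for e in entries}
        #: position of each entry in the spectrum vector, by dense code
        #: index; -1 marks the 10 non-connected codes.
        self.position_of_code: list[int] = [-1] * N_CODES
        for pos, e in enumerate(entries):
            self.position_of_code[code_index(e.code)] = pos
        self.aliases: dict[str, CatalogEntry] = {
            "fan_in_up": self._by_code[(PairState.NONE, PairState.UP, PairState.UP)],
            "up_chain": self._by_code[(PairState.UP, PairState.NONE, PairState.UP)],
            "fan_out_up": self._by_code[(PairState.UP, PairState.UP, PairState.NONE)],
        }

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries)

    def __getitem__(self, key) -> CatalogEntry:
        if isinstance(key, str):
            return self.aliases[key]
        if isinstance(key, tuple) and len(key) == 2 and all(isinstance(k, int) for k in key):
            return self._by_key[key]
        raise KeyError(key)

    @property
    def keys(self) -> list[tuple[int, int]]:
        """(q, s) labels in spectrum order."""
        return [e.key for e in self.entries]

    @property
    def n_classes(self) -> int:
        return len(self.class_index)

    def class_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for e in self.entries:
            sizes[e.class_id] = sizes.get(e.class_id, 0) + 1
        return sizes

    def class_members(self, class_id: int) -> list[CatalogEntry]:
        return [e for e in self.entries if e.class_id == class_id]

    def classify(self, code: Code) -> CatalogEntry:
        """Look up the entry for a connected code.

        Raises ``ValueError`` on a code with an isolated node; callers
        counting spectra filter those out first.
        """
        entry = self._by_code.get(tuple(PairState(s) for s in code))
        if entry is None:
            raise ValueError(
                f"code {tuple(PairState(s).name for s in code)} contains an "
                "isolated node and is not a connected substructure"
            )
        return entry

    def to_frame(self) -> pd.DataFrame:
        """Catalog as a table (one row per substructure)."""
        return pd.DataFrame(
            {
                "code": [e.code_str() for e in self.entries],
                "class_id": [e.class_id for e in self.entries],
                "member_id": [e.member_id for e in self.entries],
                "link_count": [e.link_count for e in self.entries],
                "up_count": [e.up_count for e in self.entries],
                "down_count": [e.down_count for e in self.entries],
            }
        )

    def to_json(self) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "pair_order": ["bottom-middle", "bottom-top", "middle-top"],
            "aliases": {k: list(v.key) for k, v in self.aliases.items()},
            "entries": self.to_frame().to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2)


def classify_triple(pair_states: Code, catalog: "Catalog | None" = None) -> CatalogEntry:
    """Catalog entry for a triple's pair states ((b,m), (b,t), (m,t))."""
    return (catalog or load_catalog()).classify(pair_states)


@lru_cache(maxsize=1)
def load_catalog() -> Catalog:
    """The shared catalog instance (built once per process)."""
    return Catalog()


def build_catalog() -> Catalog:
    """Construct a fresh catalog (prefer :func:`load_catalog`)."""
    return Catalog()
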