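"""Ordered 3-node motif spectra.

The spectrum of an ordered network is the vector of appearance counts
eta_(q,s) of the 54 connected ordered substructures over all node
triples, where the pair states of a triple are read off the full
network (induced-subgraph counting).  Summing over member IDs s
collapses it to the classical 13-class unordered census.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd

from .catalog import Catalog, load_catalog
from .network import OrderedNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifSpectrum:
    """Counts eta_(q,s) over the 54-entry catalog, in catalog order."""

    counts: np.ndarray
    n_nodes: int
    n_edges: int

    def __post_init__(self) -> None:
        if self.counts.shape != (len(load_catalog()),):
            raise ValueError("spectrum must have one count per catalog entry")

    def __getitem__(self, key) -> int:
        entry = load_catalog()[key]
        return int(self.counts[load_catalog().entries.index(entry)])

    @property
    def total(self) -> int:
        """Number of connected induced 3-node subgraphs."""
        return int(self.counts.sum())

    def collapse(self) -> pd.Series:
        """Unordered class counts eta_q = sum_s eta_(q,s)."""
        return collapse_spectrum(self)

    def to_frame(self) -> pd.DataFrame:
        cat = load_catalog()
        return pd.DataFrame(
            {
                "class_id": [e.class_id for e in cat],
                "member_id": [e.member_id for e in cat],
                "eta": self.counts.astype(int),
            }
        )

    def nonzero_keys(self) -> list[tuple[int, int]]:
        cat = load_catalog()
        return [e.key for e, c in zip(cat, self.counts) if c > 0]


@lru_cache(maxsize=8)
def _triples(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.fromiter(
        (i for tri in combinations(range(n), 3) for i in tri), dtype=np.intp
    ).reshape(-1, 3)
    return t[:, 0], t[:, 1], t[:, 2]


def count_codes(adjacency: np.ndarray) -> np.ndarray:
    """Histogram over all 64 configuration codes for a rank-ordered
    adjacency matrix (self-loops on the diagonal are never read)."""
    n = adjacency.shape[0]
    if n < 3:
        return np.zeros(64, dtype=np.int64)
    a, b, c = _triples(n)
    m = adjacency
    # pair state of (lo, hi) = 2*up + down, matching PairState values
    s01 = 2 * m[a, b] + m[b, a]
    s02 = 2 * m[a, c] + m[c, a]
    s12 = 2 * m[b, c] + m[c, b]
    idx = 16 * s01.astype(np.int64) + 4 * s02 + s12
    return np.bincount(idx, minlength=64)


def spectrum_from_adjacency(adjacency: np.ndarray, n_edges: int | None = None) -> MotifSpectrum:
    """Spectrum for an adjacency matrix already in rank order."""
    cat = load_catalog()
    code_counts = count_codes(adjacency)
    pos = np.asarray(cat.position_of_code)
    counts = np.zeros(len(cat), dtype=np.int64)
    mask = pos >= 0
    counts[pos[mask]] = code_counts[mask]
    if n_edges is None:
        n_edges = int(adjacency.sum())
    return MotifSpectrum(counts=counts, n_nodes=adjacency.shape[0], n_edges=n_edges)


def count_spectrum(net: OrderedNetwork, catalog: Catalog | None = None) -> MotifSpectrum:
    """Count the ordered 3-node motif spectrum of a network.

    Iterates all C(N,3) rank-ordered node triples, reads the three pair
    states from the full edge set, and increments the matching catalog
    entry; codes with an isolated node are not counted.  Self-loops are
    skipped (their number is logged).
    """
    if net.n < 3:
        warnings.warn("network has fewer than 3 nodes; spectrum is empty", stacklevel=2)
        return MotifSpectrum(
            counts=np.zeros(len(load_catalog()), dtype=np.int64),
            n_nodes=net.n,
            n_edges=net.n_edges,
        )
    if net.n_self_loops:
        logger.info("ignoring %d self-loop(s) in motif counting", net.n_self_loops)
    return spectrum_from_adjacency(net.adjacency(), n_edges=net.n_edges)


def collapse_spectrum(spec: MotifSpectrum) -> pd.Series:
    """Collapse eta_(q,s) to the 13 unordered class counts eta_q."""
    cat = load_catalog()
    out = pd.Series(0, index=pd.RangeIndex(1, cat.n_classes + 1, name="class_id"), name="eta")
    for entry, c in zip(cat, spec.counts):
        out[entry.class_id] += int(c)
    return out
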