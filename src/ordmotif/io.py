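"""Readers, writers and toy fixtures.

Edge lists are two-column delimited text (source, target), comments
starting with '#', an optional header row.  Edge direction follows the
energy-flow convention (prey -> predator); files using the opposite
"A eats B" convention can be flipped on read.  The node table is
delimited text with columns (node_id, niche_value), the niche value
being e.g. average adult body mass in whatever units the data use.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import load_catalog
from .network import OrderedNetwork
from .random_model import RandomModelParams, generate_random_network
from .spectrum import MotifSpectrum

logger = logging.getLogger(__name__)

_HEADER_WORDS = {"source", "target", "from", "to", "prey", "predator", "node", "node_id", "id"}


def _data_lines(path) -> list[list[str]]:
    rows = []
    text = Path(path).read_text()
    delim = "\t" if "\t" in text else None  # None = any whitespace/comma fallback
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(delim) if delim else line.replace(",", " ").split()
        rows.append([f.strip() for f in fields])
    if not rows:
        raise ValueError(f"{path}: no data lines")
    return rows


def read_edge_list(path, direction: str = "energy") -> list[tuple[str, str]]:
    """Read directed edges; duplicates collapse with a warning.

    ``direction="energy"`` keeps edges as written (source -> target is
    energy flow, "target eats source"); ``direction="eats"`` flips them
    (source eats target in the file).
    """
    if direction not in ("energy", "eats"):
        raise ValueError("direction must be 'energy' or 'eats'")
    rows = _data_lines(path)
    if all(w.lower() in _HEADER_WORDS for w in rows[0][:2]):
        rows = rows[1:]
    edges: list[tuple[str, str]] = []
    seen = set()
    dupes = 0
    for fields in rows:
        if len(fields) < 2:
            raise ValueError(f"{path}: edge line needs two columns, got {fields!r}")
        u, v = fields[0], fields[1]
        if direction == "eats":
            u, v = v, u
        if (u, v) in seen:
            dupes += 1
            continue
        seen.add((u, v))
        edges.append((u, v))
    if dupes:
        warnings.warn(f"{path}: collapsed {dupes} duplicate edge line(s)", stacklevel=2)
    return edges


def read_node_table(path) -> dict[str, float]:
    """Read (node_id, niche_value) rows into a dict."""
    rows = _data_lines(path)
    if rows[0][0].lower() in _HEADER_WORDS or _unparseable(rows[0]):
        rows = rows[1:]
    out: dict[str, float] = {}
    for fields in rows:
        if len(fields) < 2:
            raise ValueError(f"{path}: node line needs two columns, got {fields!r}")
        try:
            out[fields[0]] = float(fields[1])
        except ValueError as exc:
            raise ValueError(
                f"{path}: niche value {fields[1]!r} for node {fields[0]!r} is not a number"
            ) from exc
    return out


def _unparseable(fields: Sequence[str]) -> bool:
    try:
        float(fields[1])
        return False
    except (ValueError, IndexError):
        return True


def read_ordered_network(
    edges_path, nodes_path=None, direction: str = "energy"
) -> OrderedNetwork:
    """Build an ordered network from an edge list and optional node table.

    With a node table, ranks ascend in niche value (ties broken by file
    order, with a warning) and every edge endpoint must appear in the
    table.  Without one, ranks follow first appearance in the edge file.
    """
    edges = read_edge_list(edges_path, direction=direction)
    if nodes_path is None:
        return OrderedNetwork.from_edges(edges)
    niche = read_node_table(nodes_path)
    endpoints = {n for e in edges for n in e}
    missing = sorted(endpoints - niche.keys())
    if missing:
        raise ValueError(
            f"edge endpoint(s) missing from node table: {', '.join(map(str, missing[:10]))}"
        )
    return OrderedNetwork.from_edges(edges, nodes=list(niche), niche_value=niche)


def write_network(net: OrderedNetwork, edges_path, nodes_path=None, delimiter: str = "\t") -> None:
    """Write edge list (+ node table with rank / niche value)."""
    with open(edges_path, "w") as fh:
        fh.write(f"source{delimiter}target\n")
        for u, v in sorted(net.edges, key=lambda e: (net.rank(e[0]), net.rank(e[1]))):
            fh.write(f"{u}{delimiter}{v}\n")
    if nodes_path is not None:
        with open(nodes_path, "w") as fh:
            fh.write(f"node_id{delimiter}niche_value\n")
            for node in net.nodes:
                val = net.niche_value[node] if net.niche_value else net.rank(node)
                fh.write(f"{node}{delimiter}{val}\n")


def write_spectrum(spec: MotifSpectrum, path, fmt: str = "tsv", provenance: dict | None = None) -> None:
    """Write a spectrum as TSV (class_id, member_id, eta) or JSON."""
    frame = spec.to_frame()
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        payload = {
            "ordmotif_version": __version__,
            "n_nodes": spec.n_nodes,
            "n_edges": spec.n_edges,
            "provenance": provenance or {},
            "spectrum": frame.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_spectrum(path) -> MotifSpectrum:
    """Read a TSV spectrum written by :func:`write_spectrum`."""
    frame = pd.read_csv(path, sep="\t")
    cat = load_catalog()
    counts = np.zeros(len(cat), dtype=np.int64)
    for _, row in frame.iterrows():
        pos = cat.entries.index(cat[(int(row["class_id"]), int(row["member_id"]))])
        counts[pos] = int(row["eta"])
    return MotifSpectrum(counts=counts, n_nodes=0, n_edges=0)


# -- fixtures ------------------------------------------------------------

FIXTURES = ("chain3", "fan_in3", "fan_out3", "triangle3", "random6", "random10")


def make_fixture(name: str, seed: int = 1) -> OrderedNetwork:
    """Deterministic toy ordered networks for tests and examples.

    chain3: 1 -> 2 -> 3 (up-chain); fan_in3: 1 -> 3, 2 -> 3; fan_out3:
    1 -> 2, 1 -> 3; triangle3: feed-forward triangle 1 -> 2 -> 3 with
    1 -> 3 (omnivory); random6 / random10: seeded draws of the directed
    ordered random model.
    """
    if name == "chain3":
        return OrderedNetwork((1, 2, 3), frozenset({(1, 2), (2, 3)}))
    if name == "fan_in3":
        return OrderedNetwork((1, 2, 3), frozenset({(1, 3), (2, 3)}))
    if name == "fan_out3":
        return OrderedNetwork((1, 2, 3), frozenset({(1, 2), (1, 3)}))
    if name == "triangle3":
        return OrderedNetwork((1, 2, 3), frozenset({(1, 2), (2, 3), (1, 3)}))
    if name == "random6":
        return generate_random_network(RandomModelParams(6, 0.4, 0.15, seed=seed))
    if name == "random10":
        return generate_random_network(RandomModelParams(10, 0.35, 0.1, seed=seed))
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
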