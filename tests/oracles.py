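"""Independent brute-force oracles for motif counting.

These deliberately avoid the package's vectorized counting path: each
3-node induced subgraph is built explicitly from the edge set and
matched by exhaustive comparison (ordered case) or by networkx digraph
isomorphism against 13 reference graphs (unordered case).
"""

from itertools import combinations, permutations

import networkx as nx

from ordmotif.catalog import code_edges, load_catalog


def induced_triple_edges(net, triple_rank_positions):
    """Edges of the induced subgraph on three nodes, relabelled to
    {0,1,2} in ascending rank; self-loops dropped."""
    trip = [net.nodes[i] for i in triple_rank_positions]
    local = {node: k for k, node in enumerate(trip)}
    return frozenset(
        (local[u], local[v])
        for (u, v) in net.edges
        if u in local and v in local and u != v
    )


def brute_force_spectrum(net):
    """Ordered spectrum by explicit induced-subgraph matching.

    Returns a dict (class_id, member_id) -> count over all 54 entries.
    """
    cat = load_catalog()
    counts = {e.key: 0 for e in cat}
    for tri in combinations(range(net.n), 3):
        edges3 = induced_triple_edges(net, tri)
        touched = {v for e in edges3 for v in e}
        if len(touched) < 3:
            continue
        matches = [e for e in cat if code_edges(e.code) == edges3]
        assert len(matches) == 1, "every connected triple matches exactly one code"
        counts[matches[0].key] += 1
    return counts


def reference_class_digraphs():
    """One networkx DiGraph per unordered isomorphism class."""
    cat = load_catalog()
    refs = {}
    for entry in cat:
        if entry.class_id not in refs:
            g = nx.DiGraph()
            g.add_nodes_from(range(3))
            g.add_edges_from(code_edges(entry.code))
            refs[entry.class_id] = g
    return refs


def brute_force_unordered_census(net):
    """13-class census via networkx digraph isomorphism."""
    refs = reference_class_digraphs()
    counts = {q: 0 for q in refs}
    for tri in combinations(range(net.n), 3):
        edges3 = induced_triple_edges(net, tri)
        touched = {v for e in edges3 for v in e}
        if len(touched) < 3:
            continue
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        g.add_edges_from(edges3)
        hits = [q for q, ref in refs.items() if nx.is_isomorphic(g, ref)]
        assert len(hits) == 1
        counts[hits[0]] += 1
    return counts


def exhaustive_reorder_mean_oracle(net):
    """Mean spectrum over all N! rank orders, via the brute-force
    ordered counter (independent of the package's reorder_null)."""
    cat = load_catalog()
    totals = {e.key: 0 for e in cat}
    n_orders = 0
    for perm in permutations(net.nodes):
        reordered = net.with_order(perm)
        for key, c in brute_force_spectrum(reordered).items():
            totals[key] += c
        n_orders += 1
    return {key: v / n_orders for key, v in totals.items()}
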