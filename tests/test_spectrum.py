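"""Ordered spectrum counting against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ordmotif import (
    OrderedNetwork,
    RandomModelParams,
    collapse_spectrum,
    count_spectrum,
    generate_random_network,
    load_catalog,
    make_fixture,
)
from ordmotif.random_model import mirror_code

from oracles import brute_force_spectrum, brute_force_unordered_census


def test_single_up_chain():
    net = OrderedNetwork((1, 2, 3), frozenset({(1, 2), (2, 3)}))
    spec = count_spectrum(net)
    assert spec["up_chain"] == 1
    assert spec.total == 1


def test_empty_network_counts_nothing():
    net = OrderedNetwork((1, 2, 3, 4), frozenset())
    assert count_spectrum(net).total == 0


def test_fewer_than_three_nodes_warns_and_is_empty():
    net = OrderedNetwork((1, 2), frozenset({(1, 2)}))
    with pytest.warns(UserWarning, match="fewer than 3"):
        spec = count_spectrum(net)
    assert spec.total == 0


def test_self_loops_are_ignored():
    looped = OrderedNetwork((1, 2, 3), frozenset({(1, 2), (2, 3), (2, 2)}))
    plain = OrderedNetwork((1, 2, 3), frozenset({(1, 2), (2, 3)}))
    assert (count_spectrum(looped).counts == count_spectrum(plain).counts).all()


def test_spectrum_matches_brute_force_oracle(fixture_net, catalog):
    spec = count_spectrum(fixture_net)
    oracle = brute_force_spectrum(fixture_net)
    for entry, count in zip(catalog, spec.counts):
        assert count == oracle[entry.key]


def test_collapsed_spectrum_matches_isomorphism_census(fixture_net):
    collapsed = count_spectrum(fixture_net).collapse()
    oracle = brute_force_unordered_census(fixture_net)
    assert dict(collapsed) == oracle


def test_collapse_sums_members(catalog):
    net = make_fixture("random10")
    spec = count_spectrum(net)
    collapsed = collapse_spectrum(spec)
    assert collapsed.sum() == spec.total
    per_class = {}
    for entry, c in zip(catalog, spec.counts):
        per_class[entry.class_id] = per_class.get(entry.class_id, 0) + int(c)
    assert dict(collapsed) == per_class


@settings(deadline=None, max_examples=20)
@given(seed=st.integers(0, 10_000), perm_seed=st.integers(0, 10_000))
def test_collapsed_spectrum_is_order_invariant(seed, perm_seed):
    """Permuting ranks shuffles counts within classes but never across:
    the unordered census is a topological invariant."""
    net = generate_random_network(RandomModelParams(8, 0.4, 0.2, seed=seed))
    shuffled = net.shuffled_order(np.random.default_rng(perm_seed))
    assert count_spectrum(net).collapse().equals(count_spectrum(shuffled).collapse())


@settings(deadline=None, max_examples=20)
@given(seed=st.integers(0, 10_000))
def test_rank_reversal_mirrors_the_spectrum(seed):
    """Reversing the order maps each substructure's count onto its
    top-down mirror (UP <-> DOWN swap); the total is preserved."""
    cat = load_catalog()
    net = generate_random_network(RandomModelParams(8, 0.35, 0.15, seed=seed))
    spec = count_spectrum(net)
    rev = count_spectrum(net.reversed_order())
    assert spec.total == rev.total
    for entry, count in zip(cat, spec.counts):
        mirrored = cat.classify(mirror_code(entry.code))
        assert rev.counts[cat.entries.index(mirrored)] == count


def test_total_bounded_by_triples():
    net = make_fixture("random10")
    spec = count_spectrum(net)
    assert spec.total <= 10 * 9 * 8 // 6
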