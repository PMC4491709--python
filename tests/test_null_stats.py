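"""Reordering nulls and Z-score profiles."""

import numpy as np
import pytest

from ordmotif import (
    OrderedNetwork,
    count_spectrum,
    load_catalog,
    make_fixture,
    reorder_null,
    z_profile,
    z_profile_from_ensemble,
)
from ordmotif.null_stats import exhaustive_reorder_mean

from oracles import exhaustive_reorder_mean_oracle


def test_collapsed_census_invariant_across_replicates(fixture_net):
    """Reordering ranks can only move counts within isomorphism
    classes, so every replicate collapses to the same 13-vector."""
    base = count_spectrum(fixture_net).collapse()
    ens = reorder_null(fixture_net, n_perm=20, seed=0)
    cat = load_catalog()
    class_of = np.array([e.class_id for e in cat])
    for row in ens.counts:
        collapsed = {q: int(row[class_of == q].sum()) for q in range(1, 14)}
        assert collapsed == dict(base)


def test_chain_under_reordering_stays_one_chain():
    net = make_fixture("chain3")
    ens = reorder_null(net, exhaustive=True)
    assert len(ens.counts) == 6
    assert (ens.counts.sum(axis=1) == 1).all()
    chain_class = load_catalog()["up_chain"].class_id
    cols = [i for i, e in enumerate(load_catalog()) if e.class_id == chain_class]
    assert (ens.counts[:, cols].sum(axis=1) == 1).all()


def test_exhaustive_mean_matches_permutation_oracle():
    net = make_fixture("random6")
    sub = OrderedNetwork(net.nodes[:5], frozenset(
        e for e in net.edges if e[0] in net.nodes[:5] and e[1] in net.nodes[:5]))
    mean = exhaustive_reorder_mean(sub)
    oracle = exhaustive_reorder_mean_oracle(sub)
    cat = load_catalog()
    for e, m in zip(cat, mean):
        assert m == pytest.approx(oracle[e.key])


def test_sampled_null_converges_to_exhaustive():
    net = make_fixture("random6")
    sub = OrderedNetwork(net.nodes[:5], frozenset(
        e for e in net.edges if e[0] in net.nodes[:5] and e[1] in net.nodes[:5]))
    exact = exhaustive_reorder_mean(sub)
    ens = reorder_null(sub, n_perm=3000, seed=1)
    se = np.maximum(ens.sd / np.sqrt(ens.n_reps), 1e-9)
    assert (np.abs(ens.mean - exact) <= 5 * se + 1e-9).all()


def test_reorder_null_reproducible():
    net = make_fixture("random10")
    a = reorder_null(net, n_perm=10, seed=4)
    b = reorder_null(net, n_perm=10, seed=4)
    assert (a.counts == b.counts).all()


def test_exhaustive_guard():
    net = make_fixture("random10")
    with pytest.raises(ValueError, match="N <= 8"):
        reorder_null(net, exhaustive=True)


def test_z_profile_arithmetic():
    from ordmotif import MotifSpectrum

    k = len(load_catalog())
    spec = MotifSpectrum(counts=np.full(k, 10, dtype=np.int64), n_nodes=0, n_edges=0)
    prof = z_profile(spec, np.full(k, 4.0), np.full(k, 2.0))
    assert prof.z == pytest.approx(np.full(k, 3.0))


def test_z_zero_when_observed_equals_mean():
    spec = count_spectrum(make_fixture("random10"))
    prof = z_profile(spec, spec.counts.astype(float), np.ones(len(load_catalog())))
    assert prof.z == pytest.approx(np.zeros(len(load_catalog())))


def test_degenerate_entries_flagged_not_nan_propagated():
    spec = count_spectrum(make_fixture("chain3"))
    k = len(load_catalog())
    sd = np.ones(k)
    sd[0] = 0.0
    prof = z_profile(spec, np.zeros(k), sd)
    assert prof.degenerate[0]
    assert np.isnan(prof.z[0])
    assert not np.isnan(prof.z[1:]).any()
    frame = prof.to_frame()
    assert frame["degenerate"].iloc[0]


def test_z_profile_shape_mismatch():
    spec = count_spectrum(make_fixture("chain3"))
    with pytest.raises(ValueError, match="54"):
        z_profile(spec, np.zeros(5), np.ones(5))


def test_z_from_ensemble_consistent():
    net = make_fixture("random10")
    ens = reorder_null(net, n_perm=50, seed=2)
    prof = z_profile_from_ensemble(count_spectrum(net), ens)
    ok = ~prof.degenerate
    manual = (count_spectrum(net).counts[ok] - ens.mean[ok]) / ens.sd[ok]
    assert prof.z[ok] == pytest.approx(manual)
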