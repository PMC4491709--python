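"""Analytic and simulated spectra of the directed ordered random model."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ordmotif import (
    RandomModelParams,
    analytic_spectrum,
    count_spectrum,
    generate_random_network,
    load_catalog,
    pair_config_probs,
    substructure_prob,
)
from ordmotif.catalog import enumerate_codes
from ordmotif.random_model import mirror_code

probs = st.floats(0.0, 1.0, allow_nan=False)


@pytest.mark.parametrize(
    "p_up, p_down, expected",
    [
        (0.0, 0.0, (1, 0, 0, 0)),
        (1.0, 1.0, (0, 0, 0, 1)),
        (0.5, 0.5, (0.25, 0.25, 0.25, 0.25)),
    ],
)
def test_pair_config_probs_boundary_cases(p_up, p_down, expected):
    assert pair_config_probs(p_up, p_down) == pytest.approx(expected)


def test_pair_config_probs_rejects_invalid():
    with pytest.raises(ValueError):
        pair_config_probs(1.2, 0.1)


@settings(deadline=None, max_examples=50)
@given(p_up=probs, p_down=probs)
def test_code_probabilities_sum_to_one(p_up, p_down):
    total = sum(substructure_prob(c, p_up, p_down) for c in enumerate_codes())
    assert total == pytest.approx(1.0, abs=1e-9)


def test_symmetric_probability_depends_only_on_link_count(catalog):
    p = 0.2
    for e in catalog:
        expected = p**e.link_count * (1 - p) ** (6 - e.link_count)
        assert substructure_prob(e.code, p, p) == pytest.approx(expected, rel=1e-12)


@settings(deadline=None, max_examples=30)
@given(p_up=probs, p_down=probs)
def test_swapping_parameters_mirrors_the_code(p_up, p_down):
    for code in enumerate_codes():
        assert substructure_prob(code, p_up, p_down) == pytest.approx(
            substructure_prob(mirror_code(code), p_down, p_up), rel=1e-9, abs=1e-15
        )


def test_symmetric_case_has_five_levels():
    spec = analytic_spectrum(RandomModelParams(50, 0.1, 0.1))
    assert spec.distinct_levels() == 5


def test_asymmetric_case_has_thirteen_levels():
    spec = analytic_spectrum(RandomModelParams(50, 0.1, 0.03))
    assert spec.distinct_levels() == 13


def test_levels_constant_within_statistical_class(catalog):
    """Entries with equal (up_count+bidir, down_count+bidir) exponents
    share one probability; the 13 levels are exactly these classes."""
    spec = analytic_spectrum(RandomModelParams(50, 0.1, 0.03))
    by_exponents = {}
    for e, p in zip(catalog, spec.probs):
        by_exponents.setdefault((e.up_count, e.down_count), set()).add(round(p, 15))
    assert all(len(v) == 1 for v in by_exponents.values())
    assert len(by_exponents) == 13


def test_dominant_substructures_have_two_up_links(catalog):
    spec = analytic_spectrum(RandomModelParams(50, 0.1, 0.03))
    top3 = np.argsort(spec.probs)[-3:]
    for i in top3:
        e = catalog.entries[i]
        assert (e.up_count, e.down_count) == (2, 0)


def test_expected_counts_scale_with_triples():
    spec = analytic_spectrum(RandomModelParams(20, 0.3, 0.1))
    assert spec.expected == pytest.approx(comb(20, 3) * spec.probs)


def test_generator_extremes():
    assert generate_random_network(RandomModelParams(6, 0.0, 0.0, seed=0)).n_edges == 0
    full = generate_random_network(RandomModelParams(6, 1.0, 1.0, seed=0))
    assert full.n_edges == 6 * 5


def test_generator_is_reproducible():
    a = generate_random_network(RandomModelParams(12, 0.3, 0.1, seed=7))
    b = generate_random_network(RandomModelParams(12, 0.3, 0.1, seed=7))
    assert a.edges == b.edges


def test_edge_count_matches_expectation():
    params = RandomModelParams(40, 0.25, 0.1)
    rng = np.random.default_rng(3)
    reps = 200
    counts = [generate_random_network(params, rng).n_edges for _ in range(reps)]
    pairs = comb(40, 2)
    expect = pairs * (params.p_up + params.p_down)
    se = np.sqrt(pairs * (params.p_up * (1 - params.p_up) + params.p_down * (1 - params.p_down)) / reps)
    assert abs(np.mean(counts) - expect) < 4 * se


def test_simulated_mean_spectrum_tracks_analytic():
    """Reduced-size check of the simulation/theory agreement (the full
    protocol runs in the acceptance suite)."""
    params = RandomModelParams(40, 0.15, 0.05)
    ana = analytic_spectrum(params)
    rng = np.random.default_rng(11)
    reps = 60
    counts = np.array([count_spectrum(generate_random_network(params, rng)).counts for _ in range(reps)])
    bin_se = np.sqrt(comb(40, 3) * ana.probs * (1 - ana.probs) / reps)
    se = np.maximum(counts.std(axis=0, ddof=1) / np.sqrt(reps), bin_se)
    assert (np.abs(counts.mean(axis=0) - ana.expected) <= 3 * se).all()
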