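"""Trait likelihoods on IBD graphs, the unlinked null, and LOD curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ibdkit.graphs import IBDGraphSet
from ibdkit.lod import (LODCurve, QTLModel, batch_average, component_likelihood,
                        component_logliks, lod_curve, null_loglik,
                        partition_logliks, read_lod_tsv, summed_lod_curve,
                        write_lod_tsv)
from ibdkit.pedigree import Member, Pedigree

from conftest import brute_force_trait_likelihood

MODEL = QTLModel(0.3, (0.0, 1.0, 2.0), 1.0)


# ---------------------------------------------------------------------------
# component likelihood vs oracle
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("trial", range(30))
def test_elimination_matches_bruteforce(trial):
    """Exact variable elimination equals independent 2^c enumeration on
    random graphs with up to 12 classes (rel. error < 1e-10)."""
    rng = np.random.default_rng(3000 + trial)
    n = int(rng.integers(2, 10))
    nc = int(rng.integers(2, 13))
    labels = rng.integers(0, nc, 2 * n)
    traits = rng.normal(0.4, 1.3, n)
    traits[rng.random(n) < 0.25] = np.nan
    expect = brute_force_trait_likelihood(labels, traits, MODEL)
    got = component_likelihood(labels, traits, MODEL)
    assert got == pytest.approx(expect, rel=1e-10)


def test_monomorphic_locus_uses_mu0():
    m = QTLModel(0.0, (0.0, 1.0, 2.0), 1.0)
    y = np.array([0.3, -0.2, 1.1])
    v = component_likelihood(np.array([0, 1, 2, 3, 4, 5]), y, m)
    assert v == pytest.approx(np.prod(norm.pdf(y, 0.0, 1.0)), rel=1e-12)


def test_single_individual_hardy_weinberg_mixture():
    y = 0.7
    q = MODEL.q
    v = component_likelihood(np.array([0, 1]), np.array([y]), MODEL)
    hw = ((1 - q) ** 2 * norm.pdf(y, 0, 1) + 2 * q * (1 - q) * norm.pdf(y, 1, 1)
          + q ** 2 * norm.pdf(y, 2, 1))
    assert v == pytest.approx(hw, rel=1e-12)


def test_missing_traits_contribute_factor_one():
    v = component_likelihood(np.array([0, 1, 0, 1]), np.array([0.5, np.nan]), MODEL)
    w = component_likelihood(np.array([0, 1]), np.array([0.5]), MODEL)
    assert v == pytest.approx(w, rel=1e-12)


def test_vectorized_replicates_match_scalar():
    rng = np.random.default_rng(1)
    labels = np.array([0, 1, 1, 2, 0, 3])
    Y = rng.normal(0, 1, (3, 5))
    ll = component_logliks(labels, Y, MODEL)
    for r in range(5):
        assert np.exp(ll[r]) == pytest.approx(
            component_likelihood(labels, Y[:, r], MODEL), rel=1e-10)


# ---------------------------------------------------------------------------
# null likelihood
# ---------------------------------------------------------------------------


def test_null_founders_only_closed_form():
    peds = [Pedigree("f", [Member("a", None, None, 1), Member("b", None, None, 2)])]
    traits = pd.DataFrame({"r1": [0.5, -0.1]}, index=["a", "b"])
    nl = null_loglik(peds, traits, MODEL, M=25, seed=1)
    q = MODEL.q

    def hwm(y):
        return ((1 - q) ** 2 * norm.pdf(y, 0, 1) + 2 * q * (1 - q) * norm.pdf(y, 1, 1)
                + q ** 2 * norm.pdf(y, 2, 1))

    assert nl[0] == pytest.approx(np.log(hwm(0.5) * hwm(-0.1)), abs=1e-12)


def test_null_q_zero_any_pedigree(sibpair):
    m = QTLModel(0.0, (0.0, 1.0, 2.0), 1.0)
    traits = pd.DataFrame({"r1": [0.2, 0.4, -0.3, 1.0]},
                          index=["pa", "ma", "s1", "s2"])
    nl = null_loglik([sibpair], traits, m, M=10, seed=2)
    expect = np.log(norm.pdf([0.2, 0.4, -0.3, 1.0], 0, 1)).sum()
    assert nl[0] == pytest.approx(expect, abs=1e-10)


def test_null_sibpair_matches_three_state_mixture(sibpair):
    """MC null equals the exact 1/4-1/2-1/4 sharing-state mixture within
    Monte-Carlo error (and exactly in expectation thanks to caching)."""
    traits = pd.DataFrame({"r1": [np.nan, np.nan, 0.8, 1.1]},
                          index=["pa", "ma", "s1", "s2"])
    nl = null_loglik([sibpair], traits, MODEL, M=40_000, seed=3)
    y = np.array([0.8, 1.1])
    l0 = component_likelihood(np.array([0, 1, 2, 3]), y, MODEL)
    l1 = component_likelihood(np.array([0, 1, 0, 2]), y, MODEL)
    l2 = component_likelihood(np.array([0, 1, 0, 1]), y, MODEL)
    exact = np.log(0.25 * l0 + 0.5 * l1 + 0.25 * l2)
    assert nl[0] == pytest.approx(exact, abs=0.01)


# ---------------------------------------------------------------------------
# LOD curves
# ---------------------------------------------------------------------------


def _toy_graphs(K=3):
    pos = np.array([0.0, 5.0])
    rng = np.random.default_rng(5)
    reals = []
    for _ in range(K):
        reals.append([(0, rng.integers(0, 4, 8).astype(np.int32)),
                      (1, rng.integers(0, 4, 8).astype(np.int32))])
    return IBDGraphSet(["i1", "i2", "i3", "i4"], pos, reals)


def test_all_missing_traits_give_flat_zero_lod():
    graphs = _toy_graphs()
    traits = pd.DataFrame({"r1": [np.nan] * 4},
                          index=["i1", "i2", "i3", "i4"])
    with pytest.warns(UserWarning):
        curve = lod_curve(graphs, traits, MODEL, np.zeros(1))
    assert np.allclose(curve.lod, 0.0)


def test_lod_matches_hand_assembled_likelihoods():
    """K=3 hand-written graphs at 2 positions: LOD equals the full formula
    assembled with the brute-force oracle."""
    graphs = _toy_graphs(K=3)
    y = np.array([0.9, -0.2, 1.4, 0.1])
    traits = pd.DataFrame({"r1": y}, index=["i1", "i2", "i3", "i4"])
    null = null_loglik(
        [Pedigree("f", [Member(i, None, None, 1) for i in ["i1", "i2", "i3", "i4"]])],
        traits, MODEL, M=5, seed=0)
    curve = lod_curve(graphs, traits, MODEL, null)
    for pidx in range(2):
        liks = [brute_force_trait_likelihood(graphs.labels_at(k, pidx), y, MODEL)
                for k in range(3)]
        expect = np.log10(np.mean(liks)) - null[0] / np.log(10)
        assert curve.lod[pidx, 0] == pytest.approx(expect, rel=1e-9)


def test_cache_and_no_cache_are_bit_identical():
    graphs = _toy_graphs(K=4)
    rng = np.random.default_rng(6)
    traits = pd.DataFrame(rng.normal(0, 1, (4, 3)),
                          index=["i1", "i2", "i3", "i4"],
                          columns=["r1", "r2", "r3"])
    null = np.zeros(3)
    a = lod_curve(graphs, traits, MODEL, null, cache=True)
    b = lod_curve(graphs, traits, MODEL, null, cache=False)
    assert np.array_equal(a.lod, b.lod)
    assert a.cache_stats["hits"] > 0 or a.cache_stats["misses"] > 0


def test_constant_graph_computes_each_component_once():
    pos = np.linspace(0, 10, 6)
    labels = np.array([0, 1, 2, 3, 0, 2, 1, 3], dtype=np.int32)
    graphs = IBDGraphSet(["i1", "i2", "i3", "i4"], pos, [[(0, labels)]])
    traits = pd.DataFrame({"r1": [0.1, 0.4, -0.2, 0.9]},
                          index=["i1", "i2", "i3", "i4"])
    curve = lod_curve(graphs, traits, MODEL, np.zeros(1))
    assert np.allclose(curve.lod, curve.lod[0, 0])
    # one component (all classes linked), computed exactly once
    assert curve.cache_stats["misses"] == 1


def test_batch_average_trivial_and_symmetry():
    pos = np.linspace(0, 5, 4)
    c1 = LODCurve(pos, np.ones((4, 2)), ["a", "b"])
    assert np.allclose(batch_average([c1]), 1.0)
    c2 = LODCurve(pos, -np.ones((4, 2)), ["a", "b"])
    assert np.allclose(batch_average([c1, c2]), 0.0)


def test_summed_curve_adds_per_pedigree_lods():
    g = _toy_graphs(K=2)
    rng = np.random.default_rng(8)
    traits = pd.DataFrame(rng.normal(0, 1, (4, 2)),
                          index=["i1", "i2", "i3", "i4"], columns=["r1", "r2"])
    n1 = rng.normal(size=2)
    c = lod_curve(g, traits, MODEL, n1)
    s = summed_lod_curve([g, g], traits, MODEL, [n1, n1])
    assert np.allclose(s.lod, 2 * c.lod)


def test_lod_tsv_roundtrip(tmp_path):
    curve = LODCurve(np.array([0.0, 1.5, 3.0]),
                     np.array([[0.1, 0.2], [0.3, -0.4], [1.0, 2.0]]),
                     ["r1", "r2"])
    p1 = tmp_path / "lod.tsv"
    write_lod_tsv(p1, curve)
    back = read_lod_tsv(p1)
    assert np.allclose(back.lod, curve.lod)
    assert np.allclose(back.positions_cm, curve.positions_cm)
    p2 = tmp_path / "lod2.tsv"
    write_lod_tsv(p2, back)
    assert p1.read_bytes() == p2.read_bytes()
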