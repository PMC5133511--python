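"""Pairwise 15-state IBD HMM and the joint stitching sampler."""

import numpy as np
import pytest

from ibdkit.cryptic import (ANY_IBD_STATES, IBDSegmentCall, PAIR_STATE_LABELS,
                            PairwiseIBDModel, StitchModel, any_ibd_probability,
                            call_segments, pairwise_posterior, stitch)
from ibdkit.genotypes import PanelData
from ibdkit.graphs import genotype_likelihoods


def test_fifteen_states_cover_all_set_partitions():
    assert PAIR_STATE_LABELS.shape == (15, 4)
    seen = {tuple(r) for r in PAIR_STATE_LABELS}
    assert len(seen) == 15  # Bell number B(4)


def test_transition_matrix_is_stochastic_and_identity_at_zero():
    m = PairwiseIBDModel(alpha=0.07)
    assert np.allclose(m.transition(0.0), np.eye(15))
    for d in (0.1, 1.0, 25.0):
        T = m.transition(d)
        assert np.allclose(T.sum(axis=1), 1.0)
        assert np.all(T >= 0)


def test_point_mass_prior_pins_the_posterior():
    # all-distinct is the last restricted-growth state
    pi = np.zeros(15)
    all_distinct = int(np.where([len(set(map(int, r))) == 4
                                 for r in PAIR_STATE_LABELS])[0][0])
    pi[all_distinct] = 1.0
    m = PairwiseIBDModel(alpha=0.05, pi=pi)
    rng = np.random.default_rng(0)
    L = 30
    g = rng.integers(0, 3, (L, 2)).astype(np.int8)
    post, _ = pairwise_posterior(g[:, 0], g[:, 1], np.full(L, 0.5),
                                 np.linspace(0, 30, L), m)
    assert np.allclose(post[:, all_distinct], 1.0)


def test_all_missing_posterior_is_stationary():
    m = PairwiseIBDModel()
    L = 10
    g = np.full(L, -1, dtype=np.int8)
    post, ll = pairwise_posterior(g, g, np.full(L, 0.4), np.linspace(0, 9, L), m)
    assert ll == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(post, m.pi[None, :], atol=1e-12)


def test_forward_likelihood_equals_bruteforce_path_sum():
    """Exhaustive sum over 15^3 state paths on a 3-marker toy."""
    m = PairwiseIBDModel()
    freqs = np.array([0.4, 0.5, 0.6])
    pos = np.array([0.0, 1.0, 3.0])
    g1 = np.array([0, 1, 2], dtype=np.int8)
    g2 = np.array([1, 1, 0], dtype=np.int8)
    E = np.stack([genotype_likelihoods(lab, np.stack([g1, g2], 1), freqs, m.eps)
                  for lab in PAIR_STATE_LABELS])
    T1, T2 = m.transition(1.0), m.transition(2.0)
    total = 0.0
    for s0 in range(15):
        for s1 in range(15):
            for s2 in range(15):
                total += (m.pi[s0] * E[s0, 0] * T1[s0, s1] * E[s1, 1]
                          * T2[s1, s2] * E[s2, 2])
    _, ll = pairwise_posterior(g1, g2, freqs, pos, m)
    assert np.exp(ll) == pytest.approx(total, rel=1e-9)


def test_identical_genotypes_give_strong_ibd_posterior():
    rng = np.random.default_rng(1)
    L = 500
    hap = rng.integers(0, 2, (2, L))
    g = hap.sum(axis=0).astype(np.int8)
    post, _ = pairwise_posterior(g, g, np.full(L, 0.5), np.linspace(0, 100, L),
                                 PairwiseIBDModel())
    assert any_ibd_probability(post)[L // 2] > 0.99


def test_flat_likelihood_marker_matches_neighbour_conditional():
    """At a marker with missing data the posterior equals the prior given the
    neighbours — checked against a brute-force path sum on 5 markers."""
    m = PairwiseIBDModel(alpha=0.2, beta=0.1)
    rng = np.random.default_rng(2)
    L = 5
    pos = np.linspace(0, 8, L)
    g1 = rng.integers(0, 3, L).astype(np.int8)
    g2 = rng.integers(0, 3, L).astype(np.int8)
    g1[2] = g2[2] = -1
    freqs = rng.uniform(0.3, 0.7, L)
    E = np.stack([genotype_likelihoods(lab, np.stack([g1, g2], 1), freqs, m.eps)
                  for lab in PAIR_STATE_LABELS])
    Ts = [m.transition(float(d)) for d in np.diff(pos)]
    # brute-force marginal at marker 2
    marg = np.zeros(15)
    idx = [range(15)] * L
    import itertools
    for path in itertools.product(*idx):
        w = m.pi[path[0]] * E[path[0], 0]
        for j in range(1, L):
            w *= Ts[j - 1][path[j - 1], path[j]] * E[path[j], j]
        marg[path[2]] += w
    marg /= marg.sum()
    post, _ = pairwise_posterior(g1, g2, freqs, pos, m)
    assert np.allclose(post[2], marg, atol=1e-9)


# ---------------------------------------------------------------------------
# segment calling
# ---------------------------------------------------------------------------


def test_no_high_posterior_means_no_segments():
    pos = np.linspace(0, 10, 11)
    assert call_segments(np.full(11, 0.2), pos, threshold=0.8) == []


def test_single_block_endpoints():
    pos = np.linspace(0, 10, 11)
    p = np.zeros(11)
    p[3:7] = 0.95
    segs = call_segments(p, pos, threshold=0.8, pair=("A", "B"))
    assert len(segs) == 1
    assert segs[0].start_cm == pos[3] and segs[0].end_cm == pos[6]
    assert segs[0].pair == ("A", "B")


def test_small_gaps_are_merged():
    pos = np.arange(0, 3.0, 0.2)
    p = np.full(pos.size, 0.9)
    p[5] = 0.1  # flanking called markers 0.4 cM apart, below the 0.5 cM gap
    segs = call_segments(p, pos, threshold=0.8)
    assert len(segs) == 1
    # a wide gap is not merged
    p2 = np.full(pos.size, 0.9)
    p2[5:9] = 0.1
    assert len(call_segments(p2, pos, threshold=0.8)) == 2


def test_recovers_planted_segment_midpoint():
    """A planted 25 cM shared haplotype on a dense panel (0.25 cM spacing,
    chip-like) is called over its midpoint in at least 95% of replicates
    (threshold 0.8)."""
    rng = np.random.default_rng(3)
    L, lo, hi = 600, 50.0, 75.0
    pos = np.linspace(0, 150, L)
    freqs = rng.uniform(0.2, 0.8, L)
    inside = (pos >= lo) & (pos <= hi)
    hits = 0
    n_rep = 40
    for _ in range(n_rep):
        h_shared = (rng.random(L) < freqs).astype(int)
        h = [(rng.random((2, L)) < freqs).astype(int) for _ in range(2)]
        for i in range(2):
            h[i][0, inside] = h_shared[inside]
        g1 = h[0].sum(axis=0).astype(np.int8)
        g2 = h[1].sum(axis=0).astype(np.int8)
        post, _ = pairwise_posterior(g1, g2, freqs, pos, PairwiseIBDModel())
        segs = call_segments(post, pos, threshold=0.8)
        mid = (lo + hi) / 2
        if any(s.start_cm <= mid <= s.end_cm for s in segs):
            hits += 1
    assert hits / n_rep >= 0.95


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------


def _dup_panel(rng, L=400, n=2):
    hap = rng.integers(0, 2, (2, L))
    g = hap.sum(axis=0).astype(np.int8)
    G = np.tile(g[:, None], (1, n))
    return PanelData([f"m{i}" for i in range(L)], np.linspace(0, 80, L),
                     np.full(L, 0.5), [f"I{i}" for i in range(n)], G, eps=0.01)


def test_never_copy_gives_all_distinct_everywhere():
    panel = _dup_panel(np.random.default_rng(4))
    res = stitch(panel, StitchModel(nu=1.0), K=5, seed=0)
    for k in range(5):
        dense = res.graphs.dense(k)
        assert all(len(set(row.tolist())) == dense.shape[1] for row in dense)


def test_duplicated_individual_shares_at_middle_marker():
    panel = _dup_panel(np.random.default_rng(5))
    K = 40
    res = stitch(panel, StitchModel(), K=K, seed=1)
    mid = panel.n_markers // 2
    share = sum(
        bool(set(res.graphs.labels_at(k, mid)[:2].tolist())
             & set(res.graphs.labels_at(k, mid)[2:].tolist()))
        for k in range(K))
    assert share / K > 0.95
    assert res.phase_sampled


def test_sharing_is_transitive_by_construction():
    """FGL labels make IBD transitive: whenever A~B and B~C at a marker,
    A~C there too (labels, not pairwise flags)."""
    rng = np.random.default_rng(6)
    L = 300
    pos = np.linspace(0, 100, L)
    shared = rng.integers(0, 2, L)
    G = np.empty((L, 3), dtype=np.int8)
    for i in range(3):
        other = rng.integers(0, 2, L)
        G[:, i] = shared + other
    panel = PanelData([f"m{i}" for i in range(L)], pos, np.full(L, 0.5),
                      ["A", "B", "C"], G, eps=0.01)
    res = stitch(panel, StitchModel(), K=20, seed=2)
    violations = 0
    for k in range(20):
        dense = res.graphs.dense(k)
        for row in dense:
            sets = [set(row[2 * i:2 * i + 2].tolist()) for i in range(3)]
            ab = bool(sets[0] & sets[1])
            bc = bool(sets[1] & sets[2])
            ac = bool(sets[0] & sets[2])
            if ab and bc and not ac:
                # transitivity can only fail through different classes
                if (sets[0] & sets[1]) == (sets[1] & sets[2]):
                    violations += 1
    assert violations == 0


def test_planted_multiway_segment_is_recovered():
    """3 of 6 individuals share a 25 cM segment; the fraction of
    realizations in which all three share at the midpoint exceeds 0.9."""
    rng = np.random.default_rng(7)
    L = 300
    pos = np.linspace(0, 120, L)
    inside = (pos >= 47.5) & (pos <= 72.5)
    shared = rng.integers(0, 2, L)
    G = np.empty((L, 6), dtype=np.int8)
    for i in range(6):
        h0 = rng.integers(0, 2, L)
        h1 = rng.integers(0, 2, L)
        if i < 3:
            h0[inside] = shared[inside]
        G[:, i] = h0 + h1
    panel = PanelData([f"m{i}" for i in range(L)], pos, np.full(L, 0.5),
                      [f"I{i}" for i in range(6)], G, eps=0.01)
    K = 30
    res = stitch(panel, StitchModel(), K=K, seed=3)
    mid = int(np.argmin(np.abs(pos - 60.0)))
    good = 0
    for k in range(K):
        lab = res.graphs.labels_at(k, mid)
        sets = [set(lab[2 * i:2 * i + 2].tolist()) for i in range(3)]
        common = sets[0] & sets[1] & sets[2]
        good += bool(common)
    assert good / K > 0.9


def test_stitch_realizations_are_exchangeable():
    """Mean pairwise sharing at each marker agrees between the two halves
    of the realizations within Monte-Carlo error."""
    panel = _dup_panel(np.random.default_rng(8), L=150)
    K = 60
    res = stitch(panel, StitchModel(), K=K, seed=4)
    share = np.zeros((K, panel.n_markers))
    for k in range(K):
        dense = res.graphs.dense(k)
        share[k] = [bool(set(r[:2].tolist()) & set(r[2:].tolist())) for r in dense]
    a = share[:K // 2].mean(axis=0)
    b = share[K // 2:].mean(axis=0)
    se = np.sqrt(0.25 / (K // 2))
    assert np.all(np.abs(a - b) < 4 * np.sqrt(2) * se + 1e-9)


def test_stitch_rejects_bad_inputs():
    panel = _dup_panel(np.random.default_rng(9), L=50)
    with pytest.raises(ValueError):
        stitch(panel, StitchModel(), K=0, seed=0)
    with pytest.raises(ValueError):
        StitchModel(nu=0.0)
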