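"""Exact conditional IV sampling: propagation, emissions, posterior draws."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from ibdkit.genotypes import PanelData
from ibdkit.graphs import canonical_labels, genotype_likelihoods
from ibdkit.ivsampler import (MeiosisCapError, forward_loglik, iv_emission,
                              iv_partition_table, iv_to_partition, sample_ivs)
from ibdkit.pedigree import Member, Pedigree, haldane_theta

from conftest import brute_force_partition_likelihood


def _panel(ped, positions, genotypes, freqs=None, eps=0.0):
    L = len(positions)
    freqs = np.full(L, 0.5) if freqs is None else np.asarray(freqs)
    return PanelData([f"m{i}" for i in range(L)], positions, freqs,
                     ped.individuals, np.asarray(genotypes, dtype=np.int8),
                     eps=max(eps, 1e-9) if eps else 0.01)


# ---------------------------------------------------------------------------
# IV -> partition propagation
# ---------------------------------------------------------------------------


def test_founders_only_partition_ignores_iv():
    ped = Pedigree("f", [Member("a", None, None, 1), Member("b", None, None, 2)])
    assert np.array_equal(iv_to_partition([], ped), [0, 1, 2, 3])


def test_trio_both_bits_zero_forces_grandpaternal(trio):
    lab = iv_to_partition([0, 0], trio)
    # child carries father's paternal (0) and mother's paternal (2) FGLs
    assert lab.tolist() == [0, 1, 2, 3, 0, 2]


def test_three_generation_hand_trace(three_gen):
    # meioses order: fa-pat, fa-mat, c1-pat, c1-mat, c2-pat, c2-mat
    # bits: fa inherits gf-maternal(1) and gm-paternal(2);
    # c1 takes fa's slot0 (=1) and mo's slot1 (=5);
    # c2 takes fa's slot1 (=2) and mo's slot0 (=4)
    lab = iv_to_partition([1, 0, 0, 1, 1, 0], three_gen)
    assert lab.tolist() == [0, 1, 2, 3, 1, 2, 4, 5, 1, 5, 2, 4]


def test_bit_length_mismatch_raises(trio):
    with pytest.raises(ValueError):
        iv_to_partition([0], trio)


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------


def test_all_missing_emission_is_one(sibpair):
    for bits in itertools.product([0, 1], repeat=4):
        assert iv_emission(bits, sibpair, [-1, -1, -1, -1], 0.3) == 1.0


def test_mendelian_inconsistency_zero_for_all_ivs(trio):
    # parents hom-ref, child hom-alt: impossible with eps = 0
    for bits in itertools.product([0, 1], repeat=2):
        assert iv_emission(bits, trio, [0, 0, 2], 0.5, eps=0.0) == 0.0


def test_sibpair_emission_matches_founder_allele_enumeration(sibpair):
    rng = np.random.default_rng(11)
    genos = rng.integers(0, 3, 4)
    for bits in itertools.product([0, 1], repeat=4):
        lab = iv_to_partition(bits, sibpair)
        expect = brute_force_partition_likelihood(lab, genos, 0.35, 0.02)
        assert iv_emission(bits, sibpair, genos, 0.35, eps=0.02) == pytest.approx(
            expect, rel=1e-12)


# ---------------------------------------------------------------------------
# posterior sampling
# ---------------------------------------------------------------------------


def test_prior_is_uniform_without_data(trio):
    """All genotypes missing -> IV marginal uniform over 2^m states."""
    pos = np.array([0.0, 5.0, 10.0])
    panel = _panel(trio, pos, np.full((3, 3), -1))
    gs = sample_ivs(trio, panel, K=10_000, seed=5)
    # recover the sampled IV at the first marker from the partition
    counts = {}
    for k in range(gs.K):
        key = tuple(gs.labels_at(k, 0)[-2:])
        counts[key] = counts.get(key, 0) + 1
    assert len(counts) == 4
    stat, pval = chisquare(list(counts.values()))
    assert pval > 0.01


def test_no_recombination_gives_constant_paths(sibpair):
    pos = np.array([0.0, 1e-9, 2e-9])  # theta ~ 0
    rng = np.random.default_rng(0)
    panel = _panel(sibpair, pos, rng.integers(0, 3, (3, 4)), eps=0.05)
    gs = sample_ivs(sibpair, panel, K=50, seed=1)
    for k in range(gs.K):
        assert len(gs.realizations[k]) == 1


def test_sampled_marginals_match_exact_posterior(sibpair):
    """Sampled per-marker partition frequencies agree with an independently
    coded dense forward-backward posterior (TV < 0.05 at 4000 draws)."""
    L = 12
    pos = np.linspace(0, 30, L)
    rng = np.random.default_rng(3)
    G = rng.integers(0, 3, (L, 4)).astype(np.int8)
    panel = _panel(sibpair, pos, G, eps=0.02)
    table = iv_partition_table(sibpair)
    E = np.stack([genotype_likelihoods(table[s], G, panel.freqs, 0.02)
                  for s in range(16)])
    thetas = haldane_theta(np.diff(pos))
    states = np.arange(16)
    d = np.bitwise_count(states[:, None] ^ states[None, :])

    def trans(th):
        return th ** d * (1 - th) ** (4 - d)

    al = np.full(16, 1 / 16) * E[:, 0]
    al /= al.sum()
    alphas = [al]
    for j in range(1, L):
        al = trans(thetas[j - 1]).T @ al * E[:, j]
        al /= al.sum()
        alphas.append(al)
    be = np.ones(16)
    posts = [None] * L
    posts[L - 1] = alphas[-1]
    for j in range(L - 2, -1, -1):
        be = trans(thetas[j]) @ (be * E[:, j + 1])
        be /= be.max()
        p = alphas[j] * be
        posts[j] = p / p.sum()

    K = 4000
    gs = sample_ivs(sibpair, panel, K=K, seed=9, eps=0.02)
    for j in (0, L // 2, L - 1):
        freq = {}
        for k in range(K):
            key = canonical_labels(gs.labels_at(k, j)).tobytes()
            freq[key] = freq.get(key, 0) + 1
        exact = {}
        for s in range(16):
            key = canonical_labels(table[s]).tobytes()
            exact[key] = exact.get(key, 0) + posts[j][s]
        tv = 0.5 * sum(abs(freq.get(key, 0) / K - v) for key, v in exact.items())
        assert tv < 0.05, (j, tv)


def test_founder_couple_flip_symmetry(sibpair):
    """Flipping both sib bits for the same parent yields the same emission
    (classical founder-phase symmetry), hence identical canonical keys of
    the partitions restricted to the sibs."""
    rng = np.random.default_rng(12)
    genos = rng.integers(0, 3, 4)
    for bits in itertools.product([0, 1], repeat=4):
        flipped = (1 - bits[0], bits[1], 1 - bits[2], bits[3])  # paternal bits
        assert iv_emission(bits, sibpair, genos, 0.4, 0.01) == pytest.approx(
            iv_emission(flipped, sibpair, genos, 0.4, 0.01), rel=1e-12)


def test_likelihood_factorizes_over_components():
    members = [Member("a", None, None, 1), Member("b", None, None, 2),
               Member("c", "a", "b", 1),
               Member("x", None, None, 1), Member("y", None, None, 2),
               Member("z", "x", "y", 2)]
    ped = Pedigree("f", members)
    pos = np.linspace(0, 20, 6)
    rng = np.random.default_rng(4)
    G = rng.integers(0, 3, (6, 6)).astype(np.int8)
    panel = _panel(ped, pos, G, eps=0.01)
    total = forward_loglik(ped, panel, eps=0.01)
    parts = 0.0
    for comp in ped.components():
        cols = [ped.individuals.index(i) for i in comp.individuals]
        sub = PanelData(panel.markers, pos, panel.freqs, comp.individuals,
                        G[:, cols], eps=0.01)
        parts += forward_loglik(comp, sub, eps=0.01)
    assert total == pytest.approx(parts, rel=1e-12)


def test_meiosis_cap_error():
    members = [Member("f0", None, None, 1), Member("m0", None, None, 2)]
    members += [Member(f"k{i}", "f0", "m0", 1) for i in range(12)]  # 24 meioses
    ped = Pedigree("big", members)
    panel = _panel(ped, np.array([0.0, 1.0]), np.full((2, 14), -1))
    with pytest.raises(MeiosisCapError, match="split"):
        sample_ivs(ped, panel, K=1, seed=0)
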