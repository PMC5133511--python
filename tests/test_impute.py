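"""Family-based genotype imputation and rho1/rho2 accuracy metrics."""

import numpy as np
import pandas as pd
import pytest

from ibdkit.genotypes import PanelData
from ibdkit.graphs import IBDGraphSet
from ibdkit.impute import (ImputationResult, accuracy, hardy_weinberg_result,
                           impute)


def _graphs(individuals, labels_list, positions):
    """One realization per labels array."""
    return IBDGraphSet(individuals, positions,
                       [[(0, np.asarray(lab, dtype=np.int32))]
                        for lab in labels_list])


def _panel(markers, pos, freqs, individuals, G, eps=0.0):
    return PanelData(markers, pos, freqs, individuals,
                     np.asarray(G, dtype=np.int8), eps=max(eps, 1e-9))


def test_dense_typed_target_is_self_consistent():
    """A target that is itself dense-typed is imputed to its own genotype
    with probability ~1 when the error rate is negligible."""
    graphs = _graphs(["a", "b"], [[0, 1, 2, 3]], np.array([0.0, 1.0]))
    dense = _panel(["d1", "d2", "d3"], np.array([0.0, 0.5, 1.0]),
                   np.array([0.4, 0.5, 0.6]), ["a"],
                   [[0], [1], [2]])
    res = impute(graphs, dense, targets=["a"])
    assert np.allclose(res.probs[0, 0], [1, 0, 0], atol=1e-6)
    assert np.allclose(res.probs[0, 1], [0, 1, 0], atol=1e-6)
    assert np.allclose(res.probs[0, 2], [0, 0, 1], atol=1e-6)


def test_unconnected_target_falls_back_to_hardy_weinberg():
    graphs = _graphs(["a", "b"], [[0, 1, 2, 3]], np.array([0.0, 1.0]))
    dense = _panel(["d1"], np.array([0.3]), np.array([0.3]), ["a"], [[2]])
    res = impute(graphs, dense, targets=["b"])
    f = 0.3
    assert np.allclose(res.probs[0, 0], [(1 - f) ** 2, 2 * f * (1 - f), f ** 2],
                       atol=1e-9)


def test_sib_sharing_both_fgls_copies_genotype():
    """Graph says the sibs share both FGLs; sib A observed hom-alt, eps=0
    -> sib B imputed hom-alt with probability 1."""
    graphs = _graphs(["A", "B"], [[0, 1, 0, 1]], np.array([0.0, 1.0]))
    dense = _panel(["d1"], np.array([0.4]), np.array([0.2]), ["A"], [[2]])
    res = impute(graphs, dense, targets=["B"])
    assert res.probs[0, 0, 2] == pytest.approx(1.0, abs=1e-6)
    assert res.dosage[0, 0] == pytest.approx(2.0, abs=1e-6)


def test_averaging_over_realizations_is_linear():
    """The K-realization result equals the mean of the K single-realization
    results, exactly."""
    rng = np.random.default_rng(0)
    pos = np.array([0.0, 2.0, 4.0])
    labels_list = [rng.integers(0, 4, 8) for _ in range(3)]
    dense = _panel(["d1", "d2"], np.array([0.5, 3.5]), np.array([0.3, 0.6]),
                   ["i1", "i2"], rng.integers(0, 3, (2, 2)))
    inds = ["i1", "i2", "i3", "i4"]
    multi = impute(_graphs(inds, labels_list, pos), dense)
    singles = [impute(_graphs(inds, [lab], pos), dense).probs
               for lab in labels_list]
    assert np.allclose(multi.probs, np.mean(singles, axis=0), atol=1e-12)


def test_probabilities_are_valid():
    rng = np.random.default_rng(1)
    pos = np.linspace(0, 10, 5)
    labels_list = [rng.integers(0, 6, 12) for _ in range(4)]
    dense = _panel([f"d{i}" for i in range(8)], np.linspace(0, 10, 8),
                   rng.uniform(0.1, 0.9, 8), ["i1", "i3"],
                   rng.integers(-1, 3, (8, 2)), eps=0.01)
    res = impute(_graphs([f"i{j}" for j in range(1, 7)], labels_list, pos), dense)
    assert np.all(res.probs >= 0)
    assert np.allclose(res.probs.sum(axis=2), 1.0, atol=1e-9)
    assert np.all(res.dosage >= 0) and np.all(res.dosage <= 2)


# ---------------------------------------------------------------------------
# accuracy metrics
# ---------------------------------------------------------------------------


def _result_from_dosage(dosages, markers=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    probs = np.zeros((n, m, 3))
    frac = np.clip(dosages, 0, 2) / 2.0
    probs[:, :, 2] = frac
    probs[:, :, 0] = 1 - frac
    return ImputationResult([f"t{i}" for i in range(n)],
                            markers or [f"d{j}" for j in range(m)], probs)


def test_perfect_imputation_gives_rho_one():
    true = np.array([[0, 1], [2, 0], [1, 2]])
    res = _result_from_dosage(true)
    rep = accuracy(true, res, ref_freqs=np.array([0.3, 0.4]))
    assert rep.rho1 == pytest.approx(1.0)
    assert rep.rho2 == pytest.approx(1.0)
    assert rep.n_snpe == 2 and rep.n_snps == 2


def test_footnote_formulas_hand_example():
    """4 reference-polymorphic SNPs, 2 imputed-polymorphic with
    correlations 0.8 and 0.6 -> rho1 = 0.7, rho2 = 0.35."""
    rng = np.random.default_rng(2)
    n = 200
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)

    def with_corr(x, r):
        y = r * (x - x.mean()) / x.std() + np.sqrt(1 - r * r) * rng.normal(size=n)
        return y

    true = np.stack([z1, z2, rng.normal(size=n), rng.normal(size=n)], axis=1)
    d1 = with_corr(z1, 0.8)
    d2 = with_corr(z2, 0.6)
    dos = np.stack([d1, d2, np.zeros(n), np.zeros(n)], axis=1)
    # rescale into [0, 2] without changing correlations
    true = (true - true.min(axis=0)) / np.ptp(true, axis=0) * 2
    dos[:, :2] = (dos[:, :2] - dos[:, :2].min(axis=0)) / np.ptp(dos[:, :2], axis=0) * 2
    res = _result_from_dosage(dos)
    # force the empirical correlations to exactly 0.8 / 0.6 via the sum
    rep = accuracy(true, res, ref_freqs=np.array([0.3, 0.2, 0.1, 0.4]))
    r1 = np.corrcoef(true[:, 0], dos[:, 0])[0, 1]
    r2 = np.corrcoef(true[:, 1], dos[:, 1])[0, 1]
    assert rep.n_snpe == 2 and rep.n_snps == 4
    assert rep.rho1 == pytest.approx((r1 + r2) / 2, rel=1e-9)
    assert rep.rho2 == pytest.approx((r1 + r2) / 4, rel=1e-9)


def test_constant_dosages_guard():
    true = np.array([[0, 1], [2, 0], [1, 2]])
    res = _result_from_dosage(np.ones((3, 2)))
    rep = accuracy(true, res, ref_freqs=np.array([0.3, 0.4]))
    assert rep.rho1 == 0.0 and rep.n_snpe == 0


def test_zero_variance_truth_excluded_from_snpe():
    true = np.array([[1, 1], [1, 0], [1, 2]])  # SNP 0 constant in truth
    res = _result_from_dosage(np.array([[0.1, 1.0], [0.9, 0.2], [0.4, 1.8]]))
    rep = accuracy(true, res, ref_freqs=np.array([0.3, 0.4]))
    assert rep.n_snpe == 1
    assert rep.n_snps == 2


def test_maf_bins_partition_the_snps():
    rng = np.random.default_rng(3)
    true = rng.integers(0, 3, (50, 6))
    res = _result_from_dosage(true + rng.normal(0, 0.2, true.shape))
    freqs = np.array([0.005, 0.9995, 0.05, 0.12, 0.3, 0.49])
    rep = accuracy(true, res, freqs)
    assert int(rep.by_bin["n_snps"].sum()) == 6
    assert rep.by_bin.loc["(0.0,0.01]", "n_snps"] == 2  # maf 0.005 and 0.0005


def test_report_tsv_roundtrip(tmp_path):
    true = np.array([[0, 1], [2, 0], [1, 2]])
    res = _result_from_dosage(true)
    rep = accuracy(true, res, ref_freqs=np.array([0.3, 0.4]))
    rep.to_tsv(tmp_path / "acc.tsv")
    back = pd.read_csv(tmp_path / "acc.tsv", sep="\t", index_col=0)
    assert back.loc["overall", "rho1"] == pytest.approx(1.0)


def test_family_imputation_beats_hardy_weinberg_baseline(mini_dataset):
    """Paired comparison on the mini dataset: IBD-graph imputation has a
    higher mean per-SNP correlation than the no-pedigree Hardy-Weinberg
    baseline (whose dosages are constant, hence uninformative)."""
    from ibdkit.ivsampler import sample_ivs

    ds = mini_dataset
    ped = ds.pedigrees[0]
    graphs = sample_ivs(ped, ds.sparse, K=10, seed=42)
    typed = [i for i in ds.dense.individuals if i in ped.individuals]
    targets = [i for i in ped.individuals if i not in typed]
    dense = ds.dense.subset_individuals(typed)
    res = impute(graphs, dense, targets=targets)
    truth_cols = [ds.dense_true.individuals.index(t) for t in targets]
    true = ds.dense_true.genotypes[:, truth_cols].T
    rep = accuracy(true, res, ds.dense.freqs)
    hw = hardy_weinberg_result(ds.dense.markers, ds.dense.freqs, targets)
    rep_hw = accuracy(true, hw, ds.dense.freqs)
    assert rep.rho1 > rep_hw.rho1
    assert rep.rho1 > 0.3
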