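"""Impute dense-panel genotypes into sparse-only relatives and score it.

Uses conditional IV realizations of one pedigree as the IBD scaffold:
dense SNPs observed in the dense-typed members flow along shared FGL
classes to the untyped members; classes with no observed carrier fall back
to Hardy-Weinberg at the population frequency. Accuracy is the per-SNP
correlation between true genotype and imputed dosage, summarized as rho1
(over imputed-polymorphic SNPs) and rho2 (over reference-polymorphic SNPs).
"""

from ibdkit.impute import accuracy, hardy_weinberg_result, impute
from ibdkit.ivsampler import sample_ivs
from ibdkit.simulate import mini_config, simulate

ds = simulate(mini_config(seed=2))
ped = ds.pedigrees[0]
graphs = sample_ivs(ped, ds.sparse, K=15, seed=4)

typed = [i for i in ds.dense.individuals if i in ped.individuals]
targets = [i for i in ped.individuals if i not in typed]
print(f"pedigree {ped.ped_id}: {len(typed)} dense-typed, "
      f"{len(targets)} imputation targets, {ds.dense.n_markers} dense SNPs")

res = impute(graphs, ds.dense.subset_individuals(typed), targets=targets)
true_cols = [ds.dense_true.individuals.index(t) for t in targets]
truth = ds.dense_true.genotypes[:, true_cols].T

rep = accuracy(truth, res, ds.dense.freqs)
print(f"family imputation: rho1={rep.rho1:.3f} rho2={rep.rho2:.3f} "
      f"(#SNPe={rep.n_snpe}, #SNPs={rep.n_snps})")
print(rep.by_bin.round(3))

hw = hardy_weinberg_result(ds.dense.markers, ds.dense.freqs, targets)
rep_hw = accuracy(truth, hw, ds.dense.freqs)
print(f"Hardy-Weinberg baseline (no pedigree information): "
      f"rho1={rep_hw.rho1:.3f}")
# rho1 well above the baseline shows genotypes really flow through the
# pedigree IBD; the per-bin rows show the gain persists for rare variants,
# where correlation (not concordance) is the honest metric.
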