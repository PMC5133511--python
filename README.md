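# ibdkit

Identity-by-descent (IBD) graphs for quantitative-trait mapping and
genotype imputation in family studies — including the families nobody
wrote down.

Classical linkage analysis realizes location-specific IBD *within* known
pedigrees from a sparse marker panel and scores a trait model against it.
But study samples routinely contain cryptically related individuals in
different pedigrees, and the IBD they share is invisible to per-pedigree
analysis. `ibdkit` implements the full chain for exploiting it:

1. **Conditional IV sampling** — exact Lander–Green-style realization of
   inheritance vectors (hence IBD graphs) given sparse genotypes, by
   forward–backward sampling over the 2^m IV states of each pedigree
   component (no MCMC; components above a meiosis cap must be split).
2. **Cryptic IBD** — a 15-state pairwise HMM over the set-partitions of
   two individuals' four haplotype slots for screening, and a sequential
   haplotype-copying sampler (`stitch`) that realizes K *jointly
   consistent* multi-individual IBD graphs from dense genotypes, with
   transitive sharing by construction.
3. **Merging** — union-find closure of per-pedigree partitions with the
   bridge equivalences, after an allele-aware resolution of the founder
   phase symmetry on both sides.
4. **LOD mapping from graphs alone** — for a biallelic QTL model
   (q, mu0, mu1, mu2, sigma^2), each FGL class carries a latent allele and

       LOD(x) = log10[(1/K) sum_k L(y | G_k(x))] − log10 L0,

   with L0 a gene-drop (unlinked) null; contributions are cached by graph
   equivalence and summed exactly by variable elimination on the class
   graph. Once the graphs exist, neither pedigrees nor marker data are
   touched again.
5. **Family-based imputation** — dense SNPs flow along shared FGL classes
   into sparse-typed relatives, with Hardy–Weinberg fallback; accuracy is
   the per-SNP truth/dosage correlation, reported as rho1 (per
   imputed-polymorphic SNP) and rho2 (per reference-polymorphic SNP) with
   rare/uncommon/common MAF bins.
6. **A simulator** that generates the whole study — multi-pedigree
   samples, sparse/dense panels, planted cross-pedigree founder segments,
   QTL-driven trait replicates, and a ground-truth IBD record — so every
   stage is testable end to end without external data.

See `docs/methods.md` for the models and their assumptions.

## A worked example

`examples/04_merge_and_lod.py` runs the headline contrast on the built-in
mini scenario (3 pedigrees, 54 individuals, 6 cryptically related
founders sharing a hidden 20 cM segment around a QTL at 45 cM that
explains 15% of trait variance):

```
$ python examples/04_merge_and_lod.py
QTL at 45.0 cM; averaging LOD over 35.0-55.0 cM and 20 trait replicates:
  merged graphs (pedigree + cryptic IBD): +0.46
  unmerged per-pedigree graphs (summed):  +0.10
  merged, far from the QTL (baseline):    -0.04
cache: {'hits': 6544, 'misses': 1844}
```

The unmerged analysis sees only the weak within-pedigree segregation of
the risk haplotype; merging the cryptic IBD pools the carriers across
pedigrees into one class and multiplies the evidence near the QTL, while
both curves stay at zero elsewhere. The other examples cover the
simulator (`01`), conditional IV sampling (`02`), pairwise screening and
joint stitching (`03`), and imputation accuracy (`05`); each prints what
it computes and what the numbers mean.

The same stages are available as a thin CLI (`ibdkit simulate`,
`sample-ivs`, `pairwise-ibd`, `stitch`, `merge`, `lod`, `impute`,
`accuracy`, `plot-lod`); every stage reads and writes plain-text files, so
any step can be replaced by files on disk.

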