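# Methods

`ibdkit` computes quantitative-trait linkage evidence directly from
location-specific identity-by-descent (IBD) graphs, combining IBD realized
within known pedigrees with IBD inferred among individuals the pedigrees
treat as unrelated. This note documents the models, the estimators, the
numerical choices, and what the built-in simulator does and does not
emulate.

## The IBD graph

At a genomic position, the IBD state of a sample is the partition of all
haplotype slots (two per individual: slot 0 paternal, slot 1 maternal)
into founder-genome-label (FGL) classes; two slots in one class descend
from a single ancestral haplotype. An `IBDGraphSet` holds K realizations
of such partitions along a marker grid, stored as change-points: a new
record is written only where the induced set-partition changes, so a
constant stretch costs one record and the partition at any grid index is
recovered by bisection. Canonical keys (first-occurrence relabeling of a
partition restricted to a slot subset) make partitions comparable up to
class relabeling; they are the cache keys that let any likelihood
contribution equivalent across realizations or positions be computed once.

## Conditional IV sampling (within pedigrees)

For a pedigree component with m meioses the inheritance vector (IV) at a
marker is a point in {0,1}^m; the prior over IV paths is the standard HMM:
uniform start, each bit flipping independently between adjacent markers
with the Haldane recombination fraction theta = (1 - e^(-2d/100))/2 for
distance d cM, and emission equal to the single-locus genotype likelihood
of the IV's induced partition. The per-allele genotyping error is
symmetric: each allele is read correctly with probability 1 - eps
(default 0.01), and an unordered heterozygote sums its two ordered read
events. Missing genotypes contribute factor 1.

Sampling is exact: a forward pass over all 2^m states (the transition is
applied axis-by-axis in O(m 2^m)), then backward path sampling, vectorized
over draws. Emissions are evaluated once per *distinct induced partition*,
not per state. Components above the meiosis cap (default 18) raise a
capacity error advising pedigree splitting; the likelihood and the sampler
factorize exactly over components, so a large pedigree assembled from
units below the cap loses nothing but between-unit IBD, which the
simulator's structures do not contain. Founder phase is unidentifiable
from unordered genotypes (flipping a founder couple's labels preserves
every emission); realizations therefore carry arbitrary founder phase, a
fact the merge stage must and does confront.

## Cryptic IBD

**Pairwise screen.** For an ordered pair of individuals the hidden state
is one of the 15 set-partitions of their 4 slots. The chain jumps to its
stationary law pi at rate alpha per cM (transition over distance d:
e^(-alpha d) I + (1 - e^(-alpha d)) 1 pi^T), and emits the partition
genotype likelihood. pi is parameterized by a single marginal pair-IBD
probability beta: each of the 6 slot pairs is treated as independently
IBD with probability beta and the product weights are normalized over the
15 states, so beta -> 0 concentrates on all-distinct. Defaults:
alpha = 0.05/cM, beta = 0.05, eps = 0.01. Posteriors come from exact
forward-backward; segments are maximal runs with P(any cross-individual
IBD) above a threshold, merged across gaps shorter than 0.5 cM.

**Joint stitching.** K jointly consistent multi-individual realizations
come from a sequential haplotype-copying sampler: slots are processed in a
fixed order; each individual's two slots are handled *jointly* (product
state space) so unordered genotypes get an exact emission; a slot's latent
path either copies an existing slot (adopting its FGL, match probability
1 - eps) or founds a novel FGL (population-frequency emission), with
switches at rate rho per cM and novel-versus-copy choice nu at a switch
(defaults rho = 0.1/cM, nu = 0.5). Because sharing is carried by labels,
transitivity holds by construction.

Three refinements matter in practice, all driven by the fact that input
genotypes are unphased:

1. *Phase is sampled, not assumed.* Each realization samples the
   heterozygote orientations from the model posterior, with a weak
   persistence prior along the chromosome (rate `phase_rho` = 0.01/cM) so
   uninformative stretches still yield haplotype-coherent guesses. The
   output flags phases as sampled.
2. *Copy emissions marginalize unconfident source alleles.* An allele is
   confident when pinned by a homozygous genotype or copied from a
   confident allele; unconfident alleles are phase guesses, and trusting
   them would charge miscopy penalties for pure phase errors — enough, in
   experiments, to halve segment detection. Unconfident positions emit
   0.5 instead.
3. *Emission-identical sources are collapsed.* The two slots of a
   never-copied individual are indistinguishable; splitting prior mass
   between them lets different copiers adopt different labels for the
   same haplotype and silently breaks multi-way consistency. Duplicate
   source states are merged onto their first slot (their prior mass
   summed), which makes the label choice canonical.

The processing order remains a finite-K artifact of any sequential
sampler; it is exposed (`order`, and `--shuffle-order` in the CLI) rather
than hidden.

## Merging

The merged partition at a grid position is the union-find closure of the
per-pedigree partitions plus the slot equivalences asserted by the bridge
partition (down-sampled to the sparse grid by nearest position, ties to
the lower position). Merging is a coarsening of the disjoint union —
pedigree-internal sharing is never removed — and is idempotent and
order-invariant. A groups option restricts equivalences to within stated
bridge groups, mirroring analyses that merge in separate components.

Because founder phase is arbitrary on both sides, each bridge individual
needs a per-realization choice between the identity and the swapped slot
correspondence. The default is allele-aware: the bridge realization's
sampled haplotype alleles are scored, at the sparse markers (the sparse
panel must be a subset of the dense panel by marker name), against the
pedigree-side posterior class-allele frequencies given that realization's
partition and all sparse genotypes; the correspondence with the larger
log-agreement wins, ties to identity. A phase-blind (coin-flip) alignment
would be wrong for half the bridge individuals per realization and wash
out the cross-pedigree signal — the alignment is where the two phase
symmetries are reconciled, and it is the reason the merge can be
informative at all. An explicit alignment array can be supplied instead.

## LOD scores from graphs

Under a biallelic QTL model (trait-increasing allele frequency q, genotype
means mu0/mu1/mu2, residual variance sigma^2), each FGL class carries a
latent allele with prior {1-q, q} and each phenotyped individual
contributes a Normal density at the mean indexed by its two classes'
allele count. The LOD at position x is

    LOD(x) = log10[ (1/K) sum_k L(y | G_k(x)) ] - log10 L0 ,

with L0 the same likelihood under prior (unlinked) IBD: single-locus
gene-drop partitions per pedigree component, Monte-Carlo averaged over M
draws (default 10,000). Components are independent under the null, so the
average is taken per component and multiplied — the same expectation as
averaging the product, at lower variance. Cross-pedigree IBD is absent
under the null: the recorded pedigrees are the only declared
relationships, and the unmerged analysis then coincides with classical
per-pedigree linkage.

The sum over latent class alleles is evaluated by exact min-degree
variable elimination on the class graph (classes are binary variables;
individuals are pairwise factors joining their two classes; an autozygous
individual contributes a unary factor). Pedigree-derived class graphs have
small treewidth, so merged components with dozens of classes stay exact
and fast; the capacity cap (default 2^22 cells) bounds the largest
intermediate factor rather than the raw class count. Factor tables carry a
trailing replicate axis, so all trait replicates are processed in one
elimination; running maxima are factored out during elimination and
accumulated in log space, which keeps 500-individual products well inside
double precision. Contributions are memoized by (component individuals,
canonical key restricted to their phenotyped slots, implicitly the trait
matrix); curves with and without the cache are bit-identical, and cache
statistics are reported. Mixtures over K use log-sum-exp; LOD is reported
in log10.

## Family-based imputation

Dense SNPs are assigned to the nearest sparse-grid position (cM, ties
lower) — a documented simplification of flanking-interval logic whose
error shrinks as the sparse panel densifies. Within each component of the
realized partition there, FGL-allele assignments are weighted by frequency
times the observation likelihood of the dense-typed members' genotypes,
and a target's genotype probability triple is the posterior joint of its
two classes; classes untouched by data fall back to Hardy-Weinberg at the
SNP frequency. Probabilities average over K (exactly linear in the
realizations). Accuracy uses per-SNP Pearson correlation between true
genotype and imputed dosage (dosage, not best guess: concordance flatters
rare variants): rho1 divides the correlation sum by the count of
imputed-polymorphic SNPs (#SNPe), rho2 by the count of
reference-polymorphic SNPs (#SNPs); SNPs with undefined correlation
contribute 0 and are excluded from #SNPe; bins are rare (0, 0.01],
uncommon (0.01, 0.15], common (0.15, 0.5] by reference MAF.

## The simulator

The generator emulates a multi-pedigree workshop-style study. Pedigrees
are built from three-generation family units (grandparental couple, their
children, one child married to a founder spouse, grandchildren); units are
connected components below the meiosis cap. Cryptic relatedness is
planted by giving designated marry-in founders ("bridge" individuals) a
common hidden FGL on a configured interval of their paternal slot; gene
drop then propagates the segment to descendants, so cross-pedigree IBD is
segmental, transitive, and map-consistent, and the bridge founders never
appear connected in the emitted pedigree files. The hidden FGL carries the
trait-increasing allele at the QTL — the scenario in which between-family
IBD carries mapping information that no single pedigree can see.

Sparse markers are simulated in linkage equilibrium with frequencies
uniform on (0.2, 0.8); dense markers have MAF above a floor (default
0.05) and *include the sparse markers by name*, which is what lets the
merge stage align bridge haplotypes against the sparse panel. Genotypes
are emitted from true FGL alleles with per-allele error 0.005. Traits are
y = mu_g + Normal(0, sigma^2) per replicate from the true QTL genotype,
emitted pre-adjusted (no covariates). All randomness flows from one master
seed through named substreams.

Two presets fix the study conditions:

* `mini` — 3 pedigrees x 2 nine-member units (54 individuals), 60 sparse
  markers at 1.5 cM, 360 dense markers (~0.25 cM, chip-like), 6 bridge
  founders in one group sharing 20 cM around the 45 cM QTL, additive QTL
  with variance explained 0.15 (the displacement solved in closed form),
  20 trait replicates. Seconds-scale; the default for unit tests.
* `paper_emulation` — 7 pedigrees x 9 eight-member units (504
  individuals), 351 sparse markers at 0.64 cM spacing, 702 dense markers,
  21 bridge founders (3 per pedigree) in two groups — pedigrees {1..4}
  and {5..7} — sharing hidden 25 cM segments centred at 62.5 cM (sharing
  spans 50-75 cM), additive QTL at 69 cM, 200 trait replicates. The QTL's
  variance explained (0.22) is calibrated with the closed-form solver so
  the unmerged per-pedigree analysis sits at the weak-signal level (peak
  replicate-averaged LOD about 1) while the merged graphs give a strong
  regional signal — the contrast the scenario exists to exhibit.

What the simulator does **not** emulate: background linkage
disequilibrium, admixture and population-specific allele frequencies,
realistic site-frequency spectra, genotype-calling artifacts beyond the
symmetric error, and deep multi-generation pedigree loops. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated generative model, not robustness to LD-driven false IBD or to
misspecified frequencies — both of which degrade real-data performance.

## Problem sizes used in the checks

The acceptance script runs the `paper_emulation` preset once with K = 100
realizations per sampler and the first 50 trait replicates, and reports
the peak of the replicate-averaged LOD curve over 50-75 cM for merged and
unmerged graphs; with two-group bridge sharing this contrast reproduces
the qualitative picture of a strong merged signal (peak LOD well above 3)
over a weak unmerged one (around 1-2). The test suite exercises the
same contrast, null calibration (50 replicates), and region recovery (20
seeded experiments) on the `mini` preset with K = 15 and reduced null
Monte-Carlo size, sizes chosen so the whole suite runs on a laptop-class
single core in minutes.

## Known limitations

* The stitch model is a pragmatic copying sampler with exact per-step
  conditionals, not a joint Gibbs sampler; order effects and the
  phase-confidence heuristic are documented above and exposed as options.
* The 15-state pairwise model estimates nothing: alpha, beta, rho, nu are
  inputs, and no EM is provided.
* Nearest-marker assignment for imputation ignores recombination between
  a dense SNP and its anchor marker.
* X-linked inheritance, sex-specific maps, and multi-allelic markers are
  out of scope throughout.
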