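"""Quantitative-trait LOD scores computed directly from IBD graphs.

Once IBD graphs have been realized conditional on marker data, the trait
likelihood at a position needs only the graph: under a biallelic QTL model
(allele frequency q, genotype means mu0/mu1/mu2, residual variance
sigma^2), each FGL class carries a latent allele with prior q, and each
phenotyped individual contributes a Normal density determined by the
number of trait-increasing alleles on its two classes. The LOD score at a
position x is

    LOD(x) = log10[ (1/K) sum_k L(traits | G_k(x)) ] - log10 L0,

where L0 is the same likelihood averaged over prior (gene-drop) IBD at a
single unlinked locus. Component contributions are cached by the canonical
key of the induced set-partition restricted to phenotyped slots, so any
contribution equivalent across realizations or across positions is
computed once only.

The sum over latent class alleles is evaluated by exact variable
elimination on the class graph (classes are variables, individuals are
pairwise factors joining their two classes). Pedigree-derived class graphs
have small treewidth, so components with many classes remain exact; the
capacity cap bounds the largest intermediate factor instead of the raw
class count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import logsumexp

from .graphs import CapacityError, IBDGraphSet, canonical_labels
from .pedigree import Pedigree

__all__ = ["QTLModel", "LODCurve", "component_likelihood", "component_logliks",
           "partition_logliks", "null_loglik", "lod_curve", "summed_lod_curve",
           "batch_average", "write_lod_tsv", "read_lod_tsv"]

log = logging.getLogger(__name__)

DEFAULT_FACTOR_CAP = 2 ** 22  # cells per intermediate elimination factor


@dataclass
class QTLModel:
    """Biallelic trait-locus model.

    ``q`` is the frequency of the trait-increasing allele; ``mu`` holds the
    genotype means for 0, 1, 2 copies; ``sigma2`` is the residual variance.
    """

    q: float
    mu: tuple[float, float, float]
    sigma2: float

    def __post_init__(self):
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        self.mu = tuple(float(m) for m in self.mu)

    @classmethod
    def from_yaml(cls, path) -> "QTLModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(float(d["q"]), (d["mu0"], d["mu1"], d["mu2"]), float(d["sigma2"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"q": float(self.q), "mu0": self.mu[0], "mu1": self.mu[1],
                            "mu2": self.mu[2], "sigma2": float(self.sigma2)}, fh)


def _log_normal_pdf(y: np.ndarray, mu: float, sigma2: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi * sigma2) - (y - mu) ** 2 / (2 * sigma2)


# ---------------------------------------------------------------------------
# exact elimination over class-allele assignments
# ---------------------------------------------------------------------------


def _eliminate(factors: list[tuple[tuple[int, ...], np.ndarray]], R: int,
               cap: int) -> np.ndarray:
    """Sum a product of binary-variable factors (trait axis last) over all
    variables; returns per-trait log values, rescaling as it goes."""
    logscale = np.zeros(R)
    factors = list(factors)
    while True:
        variables = sorted({v for vars_, _ in factors for v in vars_})
        if not variables:
            break
        # min-degree: variable whose elimination yields the smallest scope
        best, best_scope = None, None
        for v in variables:
            scope = set()
            for vars_, _ in factors:
                if v in vars_:
                    scope.update(vars_)
            scope.discard(v)
            if best is None or len(scope) < len(best_scope):
                best, best_scope = v, scope
        touched = [(vars_, tab) for vars_, tab in factors if best in vars_]
        rest = [(vars_, tab) for vars_, tab in factors if best not in vars_]
        union = sorted(set().union(*(set(v) for v, _ in touched)))
        if (1 << len(union)) > cap:
            raise CapacityError(
                f"elimination factor over {len(union)} classes exceeds the "
                f"capacity cap ({cap} cells); reduce pedigree or bridge density"
            )
        prod = None
        for vars_, tab in touched:
            perm = [vars_.index(v) for v in union if v in vars_] + [len(vars_)]
            shape = [2 if v in vars_ else 1 for v in union] + [R]
            t = tab.transpose(perm).reshape(shape)
            prod = t if prod is None else prod * t
        summed = prod.sum(axis=union.index(best))
        new_vars = tuple(v for v in union if v != best)
        flat_max = summed.reshape(-1, R).max(axis=0)
        flat_max = np.where(flat_max > 0, flat_max, 1.0)
        logscale += np.log(flat_max)
        rest.append((new_vars, summed / flat_max))
        factors = rest
    total = np.ones(R)
    for _, tab in factors:
        total = total * tab.reshape(R)
    with np.errstate(divide="ignore"):
        return logscale + np.log(total)


def component_logliks(labels, Y, model: QTLModel,
                      cap: int = DEFAULT_FACTOR_CAP) -> np.ndarray:
    """Log trait likelihood of one partition component, per trait replicate.

    ``labels``: ``(2 n,)`` class labels for the component's individuals;
    ``Y``: ``(n, R)`` trait values with NaN for missing (a missing trait
    contributes factor 1). Returns ``(R,)`` log-likelihoods of the sum over
    latent class-allele assignments.
    """
    labels = np.asarray(labels)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, R = Y.shape
    if labels.size != 2 * n:
        raise ValueError("labels length must be 2 x number of individuals")
    q = model.q
    prior = np.array([1 - q, q])
    factors: list[tuple[tuple[int, ...], np.ndarray]] = []
    used: set[int] = set()
    for i in range(n):
        yi = Y[i]
        obs = ~np.isnan(yi)
        if not np.any(obs):
            continue
        ca, cb = int(labels[2 * i]), int(labels[2 * i + 1])
        used.update((ca, cb))
        y = np.where(obs, yi, 0.0)
        if ca == cb:  # autozygous: dosage 0 or 2
            tab = np.ones((2, R))
            for a in (0, 1):
                tab[a, obs] = np.exp(_log_normal_pdf(y[obs], model.mu[2 * a],
                                                     model.sigma2))
            factors.append(((ca,), tab))
        else:
            tab = np.ones((2, 2, R))
            for a in (0, 1):
                for b in (0, 1):
                    tab[a, b, obs] = np.exp(_log_normal_pdf(y[obs],
                                                            model.mu[a + b],
                                                            model.sigma2))
            factors.append(((ca, cb), tab))
    if not factors:
        return np.zeros(R)
    for c in sorted(used):
        factors.append(((c,), np.tile(prior[:, None], (1, R))))
    return _eliminate(factors, R, cap)


def component_likelihood(labels, traits, model: QTLModel,
                         cap: int = DEFAULT_FACTOR_CAP) -> float:
    """Trait likelihood (density) of a partition component, single replicate.

    ``traits`` is length-n with NaN for unphenotyped individuals. The value
    is the sum over alternate/reference assignments to the component's
    classes of (Hardy-Weinberg assignment prior) x (product of Normal
    densities at the implied genotype means).
    """
    ll = component_logliks(labels, np.asarray(traits, dtype=float)[:, None],
                           model, cap)
    return float(np.exp(ll[0]))


def partition_logliks(labels, Y, model: QTLModel,
                      cap: int = DEFAULT_FACTOR_CAP) -> np.ndarray:
    """Log trait likelihood of a full partition: product over class-graph
    components (handled inside the elimination, which never joins factors
    from independent components unless forced)."""
    return component_logliks(labels, Y, model, cap)


# ---------------------------------------------------------------------------
# null (unlinked) likelihood
# ---------------------------------------------------------------------------


def trait_matrix(traits: pd.DataFrame, individuals) -> np.ndarray:
    """(n, R) trait values aligned to ``individuals``; absent -> NaN."""
    Y = np.full((len(individuals), traits.shape[1]), np.nan)
    for i, iid in enumerate(individuals):
        if iid in traits.index:
            Y[i] = traits.loc[iid].to_numpy(dtype=float)
    return Y


def null_loglik(peds: list[Pedigree], traits: pd.DataFrame, model: QTLModel,
                M: int = 10_000, seed=0, cap: int = DEFAULT_FACTOR_CAP) -> np.ndarray:
    """Log-likelihood of the traits under no linkage, per replicate.

    The trait locus is unlinked to the mapped region and cross-pedigree IBD
    is absent under the null, so prior IBD at a single locus is gene-dropped
    M times per pedigree component and the likelihood is the Monte-Carlo
    average; components are independent, hence averaged separately and
    multiplied. Deterministic given ``seed``; contributions are cached by
    graph equivalence, so M is cheap for small components.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    R = traits.shape[1]
    total = np.zeros(R)
    for ped in peds:
        for comp in ped.components():
            Y = trait_matrix(traits, comp.individuals)
            if np.all(np.isnan(Y)):
                continue
            labels = _gene_drop_batch(comp, M, rng)  # (M, 2n)
            canon = np.stack([canonical_labels(row) for row in labels])
            uniq, inv, counts = np.unique(canon, axis=0, return_inverse=True,
                                          return_counts=True)
            lls = np.stack([partition_logliks(u, Y, model, cap) for u in uniq])
            total += logsumexp(lls, axis=0, b=counts[:, None]) - np.log(M)
    return total


def _gene_drop_batch(ped: Pedigree, M: int, rng) -> np.ndarray:
    """M independent single-locus gene-drop partitions, vectorized over M."""
    labels = np.empty((M, 2 * len(ped)), dtype=np.int32)
    for j, iid in enumerate(ped.founders):
        labels[:, ped.slot_index(iid, 0)] = 2 * j
        labels[:, ped.slot_index(iid, 1)] = 2 * j + 1
    bits = rng.integers(0, 2, size=(M, ped.n_meioses))
    for mi, (child, slot) in enumerate(ped.meioses):
        mem = ped.member(child)
        parent = mem.father if slot == 0 else mem.mother
        pat = labels[:, ped.slot_index(parent, 0)]
        mat = labels[:, ped.slot_index(parent, 1)]
        labels[:, ped.slot_index(child, slot)] = np.where(bits[:, mi] == 0, pat, mat)
    return labels


# ---------------------------------------------------------------------------
# LOD curves
# ---------------------------------------------------------------------------


@dataclass
class LODCurve:
    """LOD values on a position grid, one column per trait replicate."""

    positions_cm: np.ndarray
    lod: np.ndarray                       # (L, R)
    replicates: list[str]
    K: int = 0
    source: str = ""
    cache_stats: dict = field(default_factory=dict)

    @property
    def average(self) -> np.ndarray:
        """Pointwise mean LOD across replicates."""
        return self.lod.mean(axis=1)

    def region_mean(self, start_cm: float, end_cm: float) -> float:
        """Mean of the average curve over positions in [start, end] cM."""
        sel = (self.positions_cm >= start_cm) & (self.positions_cm <= end_cm)
        return float(self.average[sel].mean())


def _phenotyped_components(labels, phen_idx):
    """Split phenotyped individuals into class-graph components.

    Returns a list of (individual-index array, slot-index array) pairs,
    deterministic order.
    """
    parent: dict[int, int] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in phen_idx:
        a, b = find(int(labels[2 * i])), find(int(labels[2 * i + 1]))
        if a != b:
            parent[b] = a
    groups: dict[int, list[int]] = {}
    for i in phen_idx:
        groups.setdefault(find(int(labels[2 * i])), []).append(int(i))
    return [np.array(v) for _, v in sorted(groups.items())]


def lod_curve(graphs: IBDGraphSet, traits: pd.DataFrame, model: QTLModel,
              null: np.ndarray, cache: bool = True,
              cap: int = DEFAULT_FACTOR_CAP, source: str = "") -> LODCurve:
    """LOD curve from an IBD graph set, vectorized over trait replicates.

    ``null`` is the per-replicate null log-likelihood for the same set of
    phenotyped individuals (see :func:`null_loglik`; for merged graphs, sum
    the per-pedigree nulls). Component contributions are memoized by
    (component individuals, canonical partition key restricted to their
    slots); the memo is exact, so curves with and without caching are
    bit-identical.
    """
    null = np.asarray(null, dtype=float)
    R = traits.shape[1]
    if null.size != R:
        raise ValueError("null must have one entry per trait replicate")
    Y = trait_matrix(traits, graphs.individuals)
    phen_idx = np.nonzero(~np.all(np.isnan(Y), axis=1))[0]
    if phen_idx.size == 0:
        warnings.warn("no phenotyped individuals overlap the graphs")
    L, K = graphs.n_positions, graphs.K
    LLK = np.zeros((K, L, R))
    memo: dict[tuple, np.ndarray] = {}
    hits = misses = 0
    for k in range(K):
        cps = graphs.realizations[k]
        for ci, (start, labels) in enumerate(cps):
            end = cps[ci + 1][0] if ci + 1 < len(cps) else L
            labels = np.asarray(labels)
            total = np.zeros(R)
            for inds in _phenotyped_components(labels, phen_idx):
                slots = np.stack([2 * inds, 2 * inds + 1], axis=1).ravel()
                key = (inds.tobytes(), canonical_labels(labels, slots).tobytes())
                if cache and key in memo:
                    total += memo[key]
                    hits += 1
                else:
                    sub = canonical_labels(labels, slots)
                    val = partition_logliks(sub, Y[inds], model, cap)
                    if cache:
                        memo[key] = val
                    misses += 1
                    total += val
            LLK[k, start:end] = total
    with np.errstate(invalid="ignore"):
        mean_log = logsumexp(LLK, axis=0) - np.log(K)   # (L, R)
    lod = (mean_log - null[None, :]) / np.log(10.0)
    stats = {"hits": hits, "misses": misses}
    log.info("lod_curve: %d cache hits, %d misses", hits, misses)
    return LODCurve(graphs.positions_cm, lod, [str(c) for c in traits.columns],
                    K=K, source=source, cache_stats=stats)


def summed_lod_curve(ped_graphs: list[IBDGraphSet], traits: pd.DataFrame,
                     model: QTLModel, nulls: list[np.ndarray],
                     cache: bool = True, cap: int = DEFAULT_FACTOR_CAP) -> LODCurve:
    """Unmerged total: sum of per-pedigree LOD curves at each position."""
    if len(ped_graphs) != len(nulls):
        raise ValueError("need one null per pedigree graph set")
    curves = [lod_curve(g, traits, model, nl, cache=cache, cap=cap,
                        source=f"pedigree[{i}]")
              for i, (g, nl) in enumerate(zip(ped_graphs, nulls))]
    base = curves[0]
    lod = np.sum([c.lod for c in curves], axis=0)
    stats = {"hits": sum(c.cache_stats["hits"] for c in curves),
             "misses": sum(c.cache_stats["misses"] for c in curves)}
    return LODCurve(base.positions_cm, lod, base.replicates,
                    K=base.K, source="summed-per-pedigree", cache_stats=stats)


def batch_average(curves: list[LODCurve]) -> np.ndarray:
    """Pointwise arithmetic mean of the average curves of several LODCurves."""
    return np.mean([c.average for c in curves], axis=0)


def write_lod_tsv(path, curve: LODCurve) -> None:
    df = pd.DataFrame(curve.lod, columns=curve.replicates)
    df.insert(0, "position_cM", curve.positions_cm)
    df["average"] = curve.average
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_lod_tsv(path) -> LODCurve:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    reps = [c for c in df.columns if c not in ("position_cM", "average")]
    return LODCurve(df["position_cM"].to_numpy(), df[reps].to_numpy(), reps)
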