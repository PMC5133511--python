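"""IBD inference among individuals not connected by any pedigree.

Two stages, mirroring the screening-then-joint workflow of IBD mapping with
cryptically related samples:

* :func:`pairwise_posterior` — a 15-state HMM over the set-partitions of
  the four haplotype slots of an ordered pair of individuals, with a
  jump-to-stationarity transition (rate ``alpha`` per cM) and the partition
  genotype likelihood as emission. Used to screen pairs for shared
  segments.
* :func:`stitch` — a sequential haplotype-copying sampler that realizes K
  jointly consistent multi-individual IBD graphs: slots are processed in a
  fixed order, each slot's latent path either copies an existing haplotype
  (adopting its FGL, miscopy rate ``eps``) or founds a novel FGL
  (population-frequency emission), with copy switches at rate ``rho`` per
  cM and a novel-versus-copy choice ``nu`` at each switch. Because sharing
  is expressed through labels rather than pairwise flags, transitivity
  holds by construction.

Unphased genotypes are handled by processing an individual's two slots
jointly (product state space) with an exact unordered-genotype emission;
the phase of each realization is sampled from the model posterior and the
sampled haplotypes are returned, flagged as sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .genotypes import PanelData, MISSING
from .graphs import IBDGraphSet, genotype_likelihoods

__all__ = ["PairwiseIBDModel", "StitchModel", "IBDSegmentCall", "StitchResult",
           "PAIR_STATE_LABELS", "pairwise_posterior", "pairwise_loglik",
           "any_ibd_probability", "call_segments", "stitch"]


def _set_partitions_4() -> np.ndarray:
    """The 15 set-partitions of 4 slots as restricted-growth label rows."""
    rows = []
    for a in product(range(4), repeat=3):
        lab = (0,) + a
        # restricted growth: each label at most 1 + max of previous
        ok = all(lab[i] <= max(lab[:i]) + 1 for i in range(1, 4))
        if ok:
            rows.append(lab)
    return np.array(rows, dtype=np.int32)


#: (15, 4) label table; slots 0,1 = first individual, 2,3 = second
PAIR_STATE_LABELS = _set_partitions_4()

#: boolean mask of states with at least one cross-individual shared class
ANY_IBD_STATES = np.array([
    bool({int(r[0]), int(r[1])} & {int(r[2]), int(r[3])}) for r in PAIR_STATE_LABELS
])


def _pi_from_beta(beta: float) -> np.ndarray:
    """Stationary distribution from a single marginal pair-IBD probability.

    Each of the 6 slot pairs is treated as independently IBD with
    probability ``beta``; the weight of a partition is the product over
    slot pairs of ``beta`` (same class) or ``1 - beta`` (different), and
    the 15 weights are normalized. ``beta -> 0`` concentrates on the
    all-distinct state.
    """
    if not 0 <= beta < 1:
        raise ValueError("beta must lie in [0, 1)")
    w = np.empty(15)
    for s, lab in enumerate(PAIR_STATE_LABELS):
        v = 1.0
        for i in range(4):
            for j in range(i + 1, 4):
                v *= beta if lab[i] == lab[j] else 1.0 - beta
        w[s] = v
    return w / w.sum()


@dataclass
class PairwiseIBDModel:
    """15-state pairwise IBD model: stationary law pi, change rate, error."""

    alpha: float = 0.05       # state-change rate per cM
    eps: float = 0.01         # per-allele genotyping error
    beta: float = 0.05        # marginal pair-IBD probability behind pi
    pi: np.ndarray | None = None

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.pi is None:
            self.pi = _pi_from_beta(self.beta)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.size != 15 or np.any(self.pi < 0) or abs(self.pi.sum() - 1) > 1e-9:
            raise ValueError("pi must be a distribution over the 15 states")

    def transition(self, d_cm: float) -> np.ndarray:
        """Jump-to-stationarity transition matrix over a distance in cM."""
        e = np.exp(-self.alpha * d_cm)
        return e * np.eye(15) + (1 - e) * np.tile(self.pi, (15, 1))


def _pair_emissions(g1, g2, freqs, eps) -> np.ndarray:
    """(15, L) emission matrix for an ordered pair of genotype vectors."""
    G = np.stack([np.asarray(g1), np.asarray(g2)], axis=1)
    return np.stack([
        genotype_likelihoods(lab, G, freqs, eps) for lab in PAIR_STATE_LABELS
    ])


def pairwise_posterior(g1, g2, freqs, positions_cm, model: PairwiseIBDModel):
    """Per-marker posterior over the 15 pairwise IBD states.

    Exact forward-backward under the jump transition. Returns ``(post,
    loglik)`` with ``post`` of shape ``(L, 15)`` summing to 1 per marker;
    with all data missing the posterior is the stationary law everywhere.
    """
    positions_cm = np.asarray(positions_cm, dtype=float)
    L = positions_cm.size
    if L < 2:
        raise ValueError("need at least 2 markers")
    E = _pair_emissions(g1, g2, freqs, model.eps)
    es = np.exp(-model.alpha * np.diff(positions_cm))
    pi = model.pi
    alphas = np.empty((L, 15))
    loglik = 0.0
    a = pi * E[:, 0]
    for j in range(L):
        if j > 0:
            e = es[j - 1]
            a = (e * a + (1 - e) * a.sum() * pi) * E[:, j]
        norm = a.sum()
        if norm <= 0:
            raise ValueError(f"zero likelihood at marker index {j}")
        loglik += np.log(norm)
        a = a / norm
        alphas[j] = a
    post = np.empty((L, 15))
    b = np.ones(15)
    post[L - 1] = alphas[L - 1]
    for j in range(L - 2, -1, -1):
        e = es[j]
        v = E[:, j + 1] * b
        b = e * v + (1 - e) * float(pi @ v)
        b = b / b.max()
        p = alphas[j] * b
        post[j] = p / p.sum()
    return post, float(loglik)


def pairwise_loglik(g1, g2, freqs, positions_cm, model: PairwiseIBDModel) -> float:
    return pairwise_posterior(g1, g2, freqs, positions_cm, model)[1]


def any_ibd_probability(post: np.ndarray) -> np.ndarray:
    """P(at least one cross-individual slot pair IBD) per marker."""
    return post[:, ANY_IBD_STATES].sum(axis=1)


@dataclass(frozen=True)
class IBDSegmentCall:
    """A called IBD segment for one pair of individuals."""

    pair: tuple[str, str]
    start_cm: float
    end_cm: float
    mean_probability: float


def call_segments(post, positions_cm, threshold: float, pair=("A", "B"),
                  merge_gap_cm: float = 0.5) -> list[IBDSegmentCall]:
    """Maximal runs of markers with P(any cross-individual IBD) >= threshold.

    Runs separated by a gap smaller than ``merge_gap_cm`` are merged.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    post = np.asarray(post)
    p_any = any_ibd_probability(post) if post.ndim == 2 else post
    positions_cm = np.asarray(positions_cm, dtype=float)
    above = p_any >= threshold
    # maximal runs of consecutive above-threshold markers
    runs: list[list[int]] = []
    for i, flag in enumerate(above):
        if flag and runs and runs[-1][-1] == i - 1:
            runs[-1].append(i)
        elif flag:
            runs.append([i])
    # merge runs separated by a sub-gap stretch of low posterior
    merged: list[list[int]] = []
    for run in runs:
        if merged and positions_cm[run[0]] - positions_cm[merged[-1][-1]] < merge_gap_cm:
            merged[-1].extend(range(merged[-1][-1] + 1, run[0]))
            merged[-1].extend(run)
        else:
            merged.append(run)
    return [
        IBDSegmentCall(tuple(pair), float(positions_cm[r[0]]),
                       float(positions_cm[r[-1]]), float(np.mean(p_any[r])))
        for r in merged
    ]


# ---------------------------------------------------------------------------
# joint stitching sampler
# ---------------------------------------------------------------------------


@dataclass
class StitchModel:
    """Haplotype-copying model behind the joint stitch sampler."""

    rho: float = 0.1        # copy-switch rate per cM
    nu: float = 0.5         # P(novel FGL | switch)
    eps: float = 0.01       # miscopy / error rate
    #: persistence rate of sampled het phases in uninformative stretches;
    #: kept far below rho so phase guesses stay coherent at chromosome scale
    phase_rho: float = 0.01

    def __post_init__(self):
        if self.rho < 0 or not 0 < self.nu <= 1 or not 0 <= self.eps < 0.5:
            raise ValueError("invalid stitch model parameters")
        if self.phase_rho < 0:
            raise ValueError("phase_rho must be non-negative")


@dataclass
class StitchResult:
    """K joint IBD realizations plus the sampled haplotypes behind them."""

    graphs: IBDGraphSet
    #: per realization, (2 n, L) alternate-allele haplotypes in graph slot order
    haplotypes: list[np.ndarray]
    #: True when input genotypes were unphased and phases were sampled
    phase_sampled: bool = True
    #: marker names of the stitched panel (for aligning against other panels)
    markers: list[str] = field(default_factory=list)


def _axis_transition(M: np.ndarray, e: float, pi: np.ndarray, axis: int) -> np.ndarray:
    s = M.sum(axis=axis, keepdims=True)
    shape = [1, 1]
    shape[axis] = pi.size
    return e * M + (1 - e) * pi.reshape(shape) * s


def _sample_flat(w: np.ndarray, rng) -> int:
    flat = w.ravel()
    tot = flat.sum()
    u = rng.random() * tot
    return int(np.searchsorted(np.cumsum(flat), u))


def _stitch_one(g, src_allele, src_conf, src_fgl, freqs, e_int, pos, model,
                next_fgl, rng):
    """Sample one individual's joint slot-pair path against given sources.

    Sources are haplotype slots (alleles, confidence flags, FGL labels);
    returns the two slots' FGL label tracks, sampled alleles, confidence
    flags, and the updated novel-FGL counter.
    """
    L = g.size
    s_all = src_allele.shape[0]
    eps = model.eps
    # emission-identical sources (same confident alleles, e.g. the two slots
    # of a never-copied individual) are collapsed onto their first slot:
    # they are indistinguishable, and splitting mass between them would let
    # different copiers adopt different labels for the same haplotype
    pm_all = np.empty((s_all, L))
    if s_all:
        src = src_allele.astype(float)
        pm_all[:] = src * (1 - eps) + (1 - src) * eps
        pm_all[~src_conf] = 0.5
    keep: list[int] = []
    weight: list[int] = []
    seen: dict[bytes, int] = {}
    for j in range(s_all):
        key = pm_all[j].tobytes()
        if key in seen:
            weight[seen[key]] += 1
        else:
            seen[key] = len(keep)
            keep.append(j)
            weight.append(1)
    s = len(keep)
    src_map = np.array(keep, dtype=np.intp)
    # state 0 = novel, state j+1 = copy collapsed source j
    p_src = np.empty((s + 1, L))
    p_src[0] = freqs
    if s:
        p_src[1:] = pm_all[src_map]
    pi = np.empty(s + 1)
    pi[0] = model.nu if s else 1.0
    if s:
        pi[1:] = (1 - model.nu) / s_all * np.asarray(weight, dtype=float)
    # emissions for the joint (slot0, slot1) state, all markers
    P, Q = p_src.T, 1 - p_src.T  # (L, s+1)
    E = np.ones((L, s + 1, s + 1))
    m0, m1, m2 = g == 0, g == 1, g == 2
    E[m0] = Q[m0, :, None] * Q[m0, None, :]
    E[m2] = P[m2, :, None] * P[m2, None, :]
    E[m1] = P[m1, :, None] * Q[m1, None, :] + Q[m1, :, None] * P[m1, None, :]
    # forward
    alphas = np.empty((L, s + 1, s + 1))
    a = np.outer(pi, pi) * E[0]
    for l in range(L):
        if l > 0:
            e = e_int[l - 1]
            a = _axis_transition(_axis_transition(a, e, pi, 0), e, pi, 1)
            a = a * E[l]
        norm = a.sum()
        if norm <= 0:
            raise ValueError(f"zero stitch likelihood at marker index {l}")
        a /= norm
        alphas[l] = a
    # backward sampling of the joint path
    c0 = np.empty(L, dtype=np.intp)
    c1 = np.empty(L, dtype=np.intp)
    idx = _sample_flat(alphas[L - 1], rng)
    c0[L - 1], c1[L - 1] = divmod(idx, s + 1)
    for l in range(L - 2, -1, -1):
        e = e_int[l]
        # T(c -> c_next) = e*delta + (1-e)*pi[c_next]: constant in c except
        # for the stay term
        w0 = np.full(s + 1, (1 - e) * pi[c0[l + 1]])
        w0[c0[l + 1]] += e
        w1 = np.full(s + 1, (1 - e) * pi[c1[l + 1]])
        w1[c1[l + 1]] += e
        idx = _sample_flat(alphas[l] * np.outer(w0, w1), rng)
        c0[l], c1[l] = divmod(idx, s + 1)
    # sample the phased alleles given the path and the genotype
    a0, a1 = _sample_alleles(g, p_src, c0, c1, pos, model.phase_rho, rng)
    labs, alles, confs = [], [], []
    for path, alle in ((c0, a0), (c1, a1)):
        lab = np.empty(L, dtype=np.int32)
        copy = path > 0
        if s:
            srcs = src_map[path[copy] - 1]
            lab[copy] = src_fgl[srcs, np.nonzero(copy)[0]]
        novel = ~copy
        starts = novel & np.concatenate(([True], path[1:] != path[:-1])) \
            if L > 1 else novel
        # consecutive novel stretch = one founder segment
        run_id = np.cumsum(starts & novel) - 1
        lab[novel] = next_fgl + run_id[novel]
        next_fgl += int((starts & novel).sum())
        conf = (g == 0) | (g == 2)
        if s:
            sc = np.zeros(L, dtype=bool)
            sc[copy] = src_conf[srcs, np.nonzero(copy)[0]]
            conf = conf | sc
        labs.append(lab)
        alles.append(alle)
        confs.append(conf)
    return labs, alles, confs, next_fgl


def stitch(panel: PanelData, model: StitchModel | None = None, K: int = 100,
           seed=None, rng=None, order: list[str] | None = None) -> StitchResult:
    """Realize K jointly consistent IBD graphs on all individuals of a panel.

    Individuals are processed in ``order`` (default: panel order; order is a
    known finite-K artifact of sequential samplers, hence exposed). Returns
    change-point IBD graphs on the panel's cM grid plus the sampled
    haplotypes of each realization.
    """
    model = model or StitchModel()
    if K < 1:
        raise ValueError("K must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    inds = list(panel.individuals)
    if order is None:
        order = inds
    if sorted(order) != sorted(inds):
        raise ValueError("order must be a permutation of the panel individuals")
    n = len(inds)
    if n < 2:
        raise ValueError("stitching needs at least 2 individuals")
    L = panel.n_markers
    pos = panel.positions_cm
    freqs = panel.freqs
    e_int = np.exp(-model.rho * np.diff(pos))
    dense_sets: list[np.ndarray] = []
    haps: list[np.ndarray] = []
    for _ in range(K):
        hap_allele = np.zeros((2 * n, L), dtype=np.int8)
        hap_fgl = np.zeros((2 * n, L), dtype=np.int32)
        # an allele is *confident* when pinned by a homozygous genotype or
        # copied from a confident source allele; unconfident alleles are
        # phase guesses and are marginalized in later copy emissions
        # (trusting them would charge miscopy penalties for phase errors,
        # which destroys real sharing signals)
        hap_conf = np.zeros((2 * n, L), dtype=bool)
        next_fgl = 0
        for t, iid in enumerate(order):
            g = panel.genotypes[:, inds.index(iid)]
            src = np.arange(2 * t)
            labs, alles, confs, next_fgl = _stitch_one(
                g, hap_allele[src], hap_conf[src], hap_fgl[src],
                freqs, e_int, pos, model, next_fgl, rng)
            for u in (0, 1):
                hap_fgl[2 * t + u] = labs[u]
                hap_allele[2 * t + u] = alles[u]
                hap_conf[2 * t + u] = confs[u]
        # reorder slots from processing order to panel order
        perm = np.empty(2 * n, dtype=np.intp)
        for t, iid in enumerate(order):
            j = inds.index(iid)
            perm[2 * j] = 2 * t
            perm[2 * j + 1] = 2 * t + 1
        dense_sets.append(hap_fgl[perm].T.copy())   # (L, 2n)
        haps.append(hap_allele[perm].copy())
    graphs = IBDGraphSet.from_dense(inds, pos, dense_sets)
    return StitchResult(graphs, haps, phase_sampled=True, markers=list(panel.markers))


def _sample_alleles(g, p_src, c0, c1, pos, rho, rng):
    """Phase/allele sampling for one individual given its sampled copy path.

    Heterozygote orientations are sampled with a two-state persistence
    prior along the chromosome (switch rate ``rho`` per cM, the copy-switch
    rate), so stretches where neither slot is informatively copied still
    yield haplotype-coherent phases — later slots can copy them as
    contiguous sequences. Copy states pin the orientation through their
    source-allele probabilities; the persistence prior is symmetric, so it
    introduces no allele bias.
    """
    L = g.size
    li = np.arange(L)
    p0 = p_src[c0, li]
    p1 = p_src[c1, li]
    a0 = np.zeros(L, dtype=np.int8)
    a1 = np.zeros(L, dtype=np.int8)
    hom_alt = g == 2
    a0[hom_alt] = 1
    a1[hom_alt] = 1
    het = np.nonzero(g == 1)[0]
    if het.size:
        # state 0: (a0, a1) = (1, 0); state 1: (0, 1)
        w = np.stack([p0[het] * (1 - p1[het]), (1 - p0[het]) * p1[het]], axis=1)
        bad = w.sum(axis=1) <= 0
        w[bad] = 0.5
        # switch probability between consecutive het markers (0.5 asymptote)
        d = np.diff(pos[het])
        sw = 0.5 * -np.expm1(-2.0 * rho * d)
        m = het.size
        f = np.empty((m, 2))
        f[0] = 0.5 * w[0]
        for j in range(1, m):
            stay = 1 - sw[j - 1]
            f[j] = w[j] * (stay * f[j - 1] + sw[j - 1] * f[j - 1][::-1])
            f[j] /= f[j].sum()
        o = np.empty(m, dtype=np.int8)
        o[m - 1] = rng.random() < f[m - 1][1] / f[m - 1].sum()
        for j in range(m - 2, -1, -1):
            stay = 1 - sw[j]
            t = np.array([stay, sw[j]]) if o[j + 1] == 0 else np.array([sw[j], stay])
            p = f[j] * t
            o[j] = rng.random() < p[1] / p.sum()
        a0[het] = (o == 0).astype(np.int8)
        a1[het] = (o == 1).astype(np.int8)
    miss = np.nonzero(g == MISSING)[0]
    if miss.size:
        a0[miss] = (rng.random(miss.size) < p0[miss]).astype(np.int8)
        a1[miss] = (rng.random(miss.size) < p1[miss]).astype(np.int8)
    return a0, a1
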