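"""Exact conditional inheritance-vector sampling (the within-pedigree stage).

Realizes pedigree IBD graphs conditional on sparse-panel genotypes under
the classical inheritance-vector hidden Markov model: the prior over the
2^m IVs of an m-meiosis pedigree is uniform, each meiosis bit flips
independently between adjacent markers with the Haldane recombination
fraction, and the emission is the partition genotype likelihood of the IV's
induced FGL partition. Sampling is an exact forward pass followed by
backward path sampling — no MCMC — which is why the number of meioses per
connected pedigree component is capped (default 18, ~2.6e5 states). Larger
pedigrees must be split into components below the cap; the sampler
factorizes over components automatically.
"""

from __future__ import annotations

import numpy as np

from .genotypes import PanelData, MISSING
from .graphs import IBDGraphSet, canonical_labels, genotype_likelihoods
from .pedigree import Pedigree, haldane_theta

__all__ = ["iv_to_partition", "iv_partition_table", "iv_emission",
           "sample_ivs", "forward_loglik", "MeiosisCapError"]

DEFAULT_MEIOSIS_CAP = 18


class MeiosisCapError(RuntimeError):
    """Pedigree component too large for exact IV enumeration."""


def iv_to_partition(bits, ped: Pedigree) -> np.ndarray:
    """Map an inheritance vector to the FGL partition it induces.

    ``bits[i]`` is the grandparental origin of meiosis ``i`` in the
    pedigree's deterministic meiosis order (0 = grandpaternal). Founder
    slots carry fixed distinct FGLs; each child slot inherits the parent's
    paternal FGL when its bit is 0, maternal when 1.
    """
    bits = np.asarray(bits).astype(np.int8).ravel()
    if bits.size != ped.n_meioses:
        raise ValueError(
            f"IV has {bits.size} bits but pedigree {ped.ped_id!r} has "
            f"{ped.n_meioses} meioses"
        )
    return iv_partition_table(ped, states=_bits_to_state(bits))[0]


def _bits_to_state(bits) -> np.ndarray:
    return np.array([int(np.sum(np.asarray(bits) << np.arange(len(bits))))])


def iv_partition_table(ped: Pedigree, states=None, cap: int = 25) -> np.ndarray:
    """FGL partitions induced by IVs, vectorized over states.

    ``states`` defaults to all ``2^m`` integers; bit ``i`` of a state is
    meiosis ``i``. Returns an ``(n_states, 2 n)`` int32 label array with
    founder ``j`` contributing FGLs ``2 j`` and ``2 j + 1``.
    """
    m = ped.n_meioses
    if states is None:
        if m > cap:
            raise MeiosisCapError(f"2^{m} IV states exceed the table cap 2^{cap}")
        states = np.arange(1 << m, dtype=np.int64)
    states = np.asarray(states, dtype=np.int64)
    S = states.size
    labels = np.empty((S, 2 * len(ped)), dtype=np.int32)
    for j, iid in enumerate(ped.founders):
        labels[:, ped.slot_index(iid, 0)] = 2 * j
        labels[:, ped.slot_index(iid, 1)] = 2 * j + 1
    for mi, (child, slot) in enumerate(ped.meioses):
        mem = ped.member(child)
        parent = mem.father if slot == 0 else mem.mother
        b = ((states >> mi) & 1).astype(bool)
        pat = labels[:, ped.slot_index(parent, 0)]
        mat = labels[:, ped.slot_index(parent, 1)]
        labels[:, ped.slot_index(child, slot)] = np.where(b, mat, pat)
    return labels


def iv_emission(bits, ped: Pedigree, genotypes, freq, eps=0.01) -> float:
    """Single-marker emission P(genotypes | IV): the partition likelihood of
    the induced FGL partition (components multiply inside)."""
    from .graphs import partition_genotype_likelihood

    return partition_genotype_likelihood(iv_to_partition(bits, ped), genotypes, freq, eps)


# ---------------------------------------------------------------------------
# forward-backward machinery
# ---------------------------------------------------------------------------


def _panel_genotypes(ped: Pedigree, panel: PanelData) -> np.ndarray:
    """(L, n_ped) genotype matrix aligned to pedigree members; individuals
    absent from the panel are fully missing."""
    G = np.full((panel.n_markers, len(ped)), MISSING, dtype=np.int8)
    col = {iid: i for i, iid in enumerate(panel.individuals)}
    for i, iid in enumerate(ped.individuals):
        if iid in col:
            G[:, i] = panel.genotypes[:, col[iid]]
    return G


def _state_emissions(ped: Pedigree, panel: PanelData, eps: float):
    """Emission matrix over IV states, computed once per distinct partition.

    Returns ``(labels_table, E)`` where ``E`` is ``(S, L)``. Distinct
    induced set-partitions are detected by canonicalization so the genotype
    likelihood is evaluated once per equivalence class of IVs.
    """
    table = iv_partition_table(ped)
    canon = np.stack([canonical_labels(row) for row in table])
    uniq, inverse = np.unique(canon, axis=0, return_inverse=True)
    G = _panel_genotypes(ped, panel)
    E_u = np.stack([
        genotype_likelihoods(u, G, panel.freqs, eps) for u in uniq
    ])  # (U, L)
    return table, E_u[inverse]


def _transition_apply(alpha: np.ndarray, theta: float, m: int) -> np.ndarray:
    """Apply the IV transition over one interval: each bit flips w.p. theta."""
    if theta == 0.0 or m == 0:
        return alpha
    a = alpha.reshape((2,) * m)
    for ax in range(m):
        a = (1 - theta) * a + theta * np.flip(a, axis=ax)
    return a.reshape(-1)


def _forward(ped: Pedigree, panel: PanelData, eps: float, cap: int):
    m = ped.n_meioses
    if m > cap:
        raise MeiosisCapError(
            f"pedigree component of {ped.ped_id!r} has {m} meioses, above the "
            f"exact-sampling cap {cap}; split the pedigree into smaller "
            "components (the sampler factorizes over components)"
        )
    thetas = haldane_theta(np.diff(panel.positions_cm))
    table, E = _state_emissions(ped, panel, eps)
    S, L = 1 << m, panel.n_markers
    dtype = np.float64 if S * L <= 2**25 else np.float32
    alphas = np.empty((L, S), dtype=dtype)
    loglik = 0.0
    alpha = np.full(S, 1.0 / S) * E[:, 0]
    for j in range(L):
        if j > 0:
            alpha = _transition_apply(alpha, float(thetas[j - 1]), m) * E[:, j]
        norm = alpha.sum()
        if norm <= 0:
            raise ValueError(
                f"genotype data impossible under the model at marker "
                f"{panel.markers[j]!r} (check error rate / pedigree)"
            )
        loglik += np.log(norm)
        alpha = alpha / norm
        alphas[j] = alpha
    return table, thetas, alphas, float(loglik)


def forward_loglik(ped: Pedigree, panel: PanelData, eps=None,
                   cap: int = DEFAULT_MEIOSIS_CAP) -> float:
    """Log P(panel genotypes | pedigree) under the IV HMM; sums over
    connected components (the likelihood factorizes)."""
    eps = panel.eps if eps is None else eps
    return float(sum(_forward(c, panel, eps, cap)[3] for c in ped.components()))


def _backward_sample(table, thetas, alphas, K: int, rng) -> np.ndarray:
    """Sample K IV paths from the exact posterior; returns (K, L) states."""
    L, S = alphas.shape
    m = int(np.log2(S)) if S > 1 else 0
    paths = np.empty((K, L), dtype=np.int64)
    w = alphas[L - 1].astype(np.float64)
    paths[:, L - 1] = _sample_columns(np.repeat(w[:, None], K, axis=1), rng)
    states = np.arange(S, dtype=np.int64)
    for j in range(L - 2, -1, -1):
        theta = float(thetas[j])
        d = np.bitwise_count(states[:, None] ^ paths[:, j + 1][None, :])
        pw = np.power(theta, np.arange(m + 1)) * np.power(1 - theta, m - np.arange(m + 1))
        w = alphas[j].astype(np.float64)[:, None] * pw[d]
        paths[:, j] = _sample_columns(w, rng)
    return paths


def _sample_columns(w: np.ndarray, rng) -> np.ndarray:
    """Draw one index per column of a non-negative weight matrix (S, K)."""
    cum = np.cumsum(w, axis=0)
    u = rng.random(w.shape[1]) * cum[-1]
    return (cum > u[None, :]).argmax(axis=0)


def sample_ivs(ped: Pedigree, panel: PanelData, K: int, seed=None, rng=None,
               eps: float | None = None, cap: int = DEFAULT_MEIOSIS_CAP) -> IBDGraphSet:
    """Draw K IBD-graph realizations conditional on sparse-panel genotypes.

    Each realization is an exact draw from P(IV path | genotypes) under the
    inheritance-vector HMM, converted to FGL partitions and stored in
    change-point form (a change-point only where the induced set-partition
    changes). Multi-component pedigrees are sampled per component with
    disjoint FGL namespaces.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = panel.eps if eps is None else eps
    comps = ped.components()
    L = panel.n_markers
    n = len(ped)
    col_of = {iid: i for i, iid in enumerate(ped.individuals)}
    dense = np.empty((K, L, 2 * n), dtype=np.int32)
    fgl_offset = 0
    for comp in comps:
        table, thetas, alphas, _ = _forward(comp, panel, eps, cap)
        paths = _backward_sample(table, thetas, alphas, K, rng)
        slot_cols = np.array(
            [2 * col_of[iid] + s for iid in comp.individuals for s in (0, 1)]
        )
        comp_slot_order = np.array(
            [comp.slot_index(iid, s) for iid in comp.individuals for s in (0, 1)]
        )
        lab = table[paths][:, :, comp_slot_order] + fgl_offset  # (K, L, 2nc)
        dense[:, :, slot_cols] = lab
        fgl_offset += 2 * comp.n_founders
    return IBDGraphSet.from_dense(ped.individuals, panel.positions_cm,
                                  [dense[k] for k in range(K)])
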