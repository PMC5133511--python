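"""IBD graphs: location-specific partitions of haplotype slots into FGL classes.

An :class:`IBDGraphSet` holds K realizations of such partitions along a
marker grid, stored as change-points (a new partition is recorded only
where the induced set-partition differs from the previous one). The module
also provides the single-locus genotype likelihood of a partition — the
emission shared by the conditional IV sampler, the pairwise cryptic-IBD
HMM, and family-based imputation — and canonical keys that make two
partitions comparable up to class relabeling, which is what lets LOD
contributions be computed once per distinct graph.
"""

from __future__ import annotations

import bisect
from typing import Sequence

import numpy as np

from .genotypes import obs_given_dosage

__all__ = [
    "CapacityError",
    "canonical_labels",
    "canonical_key",
    "partition_genotype_likelihood",
    "genotype_likelihoods",
    "class_allele_marginals",
    "class_pair_joints",
    "IBDGraphSet",
    "read_graphs",
    "write_graphs",
    "nearest_positions",
]


class CapacityError(RuntimeError):
    """A component exceeds the configured enumeration/elimination capacity."""


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------


def canonical_labels(labels, subset=None) -> np.ndarray:
    """Relabel classes by first occurrence over ``subset`` (default: all slots).

    Two partitions inducing the same set-partition of the subset map to the
    same array, whatever their raw class labels.
    """
    labels = np.asarray(labels)
    if subset is not None:
        labels = labels[np.asarray(subset)]
    uniq, first, inv = np.unique(labels, return_index=True, return_inverse=True)
    rank = np.empty(uniq.size, dtype=np.int32)
    rank[np.argsort(first)] = np.arange(uniq.size, dtype=np.int32)
    return rank[inv]


def canonical_key(labels, subset=None) -> bytes:
    """Hashable token for the set-partition induced on ``subset``.

    Stable across processes: it is the bytes of the first-occurrence
    relabeling of the subset.
    """
    if subset is not None and len(subset) == 0:
        raise ValueError("subset must be non-empty")
    return canonical_labels(labels, subset).tobytes()


# ---------------------------------------------------------------------------
# single-locus genotype likelihood of a partition
# ---------------------------------------------------------------------------


def _class_components(pair_classes: np.ndarray) -> list[np.ndarray]:
    """Split classes into components connected through individuals.

    ``pair_classes`` is an ``(n, 2)`` array of the class ids carried by each
    individual's two slots. Returns a list of arrays of class ids.
    """
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pair_classes:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for c in parent:
        groups.setdefault(find(c), []).append(c)
    return [np.array(sorted(v)) for _, v in sorted(groups.items())]


def _component_weights(cidx: np.ndarray, pair_classes: np.ndarray, obs: np.ndarray,
                       freqs: np.ndarray, T: np.ndarray, cap: int):
    """Posterior-proportional weights over allele assignments of one component.

    Returns ``(bits, W)`` where ``bits`` is ``(2^c, c)`` in the order of
    ``cidx`` and ``W`` is ``(L, 2^c)`` = prior x observation likelihood
    (unnormalized posterior). ``obs`` is ``(L, n)`` with missing coded 3.
    """
    c = cidx.size
    if c > cap:
        raise CapacityError(
            f"component with {c} allele classes exceeds the enumeration cap {cap}"
        )
    pos = {int(cl): i for i, cl in enumerate(cidx)}
    S = 1 << c
    bits = ((np.arange(S)[:, None] >> np.arange(c)[None, :]) & 1).astype(np.int8)
    k = bits.sum(axis=1)
    p = freqs[:, None]
    W = p ** k[None, :] * (1 - p) ** (c - k)[None, :]  # (L, S) prior
    members = [i for i, (a, b) in enumerate(pair_classes)
               if int(a) in pos and int(b) in pos]
    for i in members:
        a, b = pair_classes[i]
        d = bits[:, pos[int(a)]] + bits[:, pos[int(b)]]  # (S,)
        W *= T[d][:, obs[:, i]].T  # (L, S)
    return bits, W


def genotype_likelihoods(labels, genotypes, freqs, eps=0.01, cap=20) -> np.ndarray:
    """Vectorized single-locus likelihoods of unordered genotypes given a partition.

    ``labels``: ``(2 n,)`` class labels (slot order paternal, maternal per
    individual); ``genotypes``: ``(L, n)`` in {0,1,2,-1}; ``freqs``: ``(L,)``
    alternate-allele frequencies. Returns ``(L,)`` — at each marker, the sum
    over alternate/reference assignments to the FGL classes of (assignment
    prior) x (per-allele-error observation probability), multiplied over the
    components of the class graph. Classes carried only by fully missing
    individuals integrate to 1.
    """
    labels = np.asarray(labels)
    G = np.asarray(genotypes)
    if G.ndim == 1:
        G = G[None, :]
    L, n = G.shape
    if labels.size != 2 * n:
        raise ValueError("labels length must be 2 x number of individuals")
    freqs = np.broadcast_to(np.asarray(freqs, dtype=float), (L,))
    T = obs_given_dosage(eps)
    obs = np.where(G < 0, 3, G).astype(np.intp)
    ever = np.any(G >= 0, axis=0)
    out = np.ones(L)
    if not np.any(ever):
        return out
    pair_classes = labels.reshape(n, 2)[ever]
    for cidx in _class_components(pair_classes):
        _, W = _component_weights(cidx, labels.reshape(n, 2), obs, freqs, T, cap)
        out *= W.sum(axis=1)
    return out


def partition_genotype_likelihood(labels, genotypes, p, eps=0.0, cap=20) -> float:
    """Probability of unordered biallelic genotypes at one locus given a partition.

    ``genotypes`` is length-n with -1 for unobserved individuals; ``p`` is
    the alternate-allele frequency. See :func:`genotype_likelihoods`.
    """
    return float(genotype_likelihoods(labels, np.asarray(genotypes)[None, :],
                                      np.array([p]), eps, cap)[0])


def class_allele_marginals(labels, genotypes, freqs, eps=0.01, cap=20):
    """Posterior P(class allele = alt) per marker given observed genotypes.

    Returns ``(marg, class_ids)`` with ``marg`` of shape ``(L, n_classes)``
    covering every class present in ``labels`` (classes untouched by data
    keep their Hardy-Weinberg prior ``freqs``).
    """
    labels = np.asarray(labels)
    G = np.asarray(genotypes)
    if G.ndim == 1:
        G = G[None, :]
    L, n = G.shape
    freqs = np.broadcast_to(np.asarray(freqs, dtype=float), (L,)).astype(float)
    class_ids = np.unique(labels)
    marg = np.tile(freqs[:, None], (1, class_ids.size))
    T = obs_given_dosage(eps)
    obs = np.where(G < 0, 3, G).astype(np.intp)
    ever = np.any(G >= 0, axis=0)
    if not np.any(ever):
        return marg, class_ids
    col = {int(c): i for i, c in enumerate(class_ids)}
    pair_classes = labels.reshape(n, 2)[ever]
    for cidx in _class_components(pair_classes):
        bits, W = _component_weights(cidx, labels.reshape(n, 2), obs, freqs, T, cap)
        tot = W.sum(axis=1)
        tot = np.where(tot <= 0, 1.0, tot)
        for j, cl in enumerate(cidx):
            marg[:, col[int(cl)]] = (W * bits[:, j][None, :]).sum(axis=1) / tot
    return marg, class_ids


def class_pair_joints(labels, genotypes, freqs, pairs, eps=0.01, cap=20) -> np.ndarray:
    """Joint posterior of the alleles of class pairs, per marker.

    ``pairs`` is a sequence of ``(class_a, class_b)`` label pairs. Returns
    ``(L, len(pairs), 2, 2)`` with axis 2 = allele of a, axis 3 = allele of
    b. Pairs split across independent components factorize; classes with no
    data take their Hardy-Weinberg prior.
    """
    labels = np.asarray(labels)
    G = np.asarray(genotypes)
    if G.ndim == 1:
        G = G[None, :]
    L, n = G.shape
    freqs = np.broadcast_to(np.asarray(freqs, dtype=float), (L,)).astype(float)
    T = obs_given_dosage(eps)
    obs = np.where(G < 0, 3, G).astype(np.intp)
    ever = np.any(G >= 0, axis=0)
    pair_classes = labels.reshape(n, 2)[ever]
    comps = _class_components(pair_classes) if np.any(ever) else []
    where = {int(cl): ci for ci, cidx in enumerate(comps) for cl in cidx}
    # per-component cached weights
    cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def comp_data(ci):
        if ci not in cache:
            cidx = comps[ci]
            bits, W = _component_weights(cidx, labels.reshape(n, 2), obs, freqs, T, cap)
            tot = W.sum(axis=1)
            cache[ci] = (cidx, bits, W / np.where(tot <= 0, 1.0, tot)[:, None])
        return cache[ci]

    def marginal(cl):
        ci = where.get(int(cl))
        if ci is None:
            return np.stack([1 - freqs, freqs], axis=1)  # (L, 2) prior
        cidx, bits, Wn = comp_data(ci)
        j = int(np.where(cidx == cl)[0][0])
        p1 = (Wn * bits[:, j][None, :]).sum(axis=1)
        return np.stack([1 - p1, p1], axis=1)

    out = np.empty((L, len(pairs), 2, 2))
    for pi, (ca, cb) in enumerate(pairs):
        ci_a, ci_b = where.get(int(ca)), where.get(int(cb))
        if ca == cb:
            m = marginal(ca)
            out[:, pi] = 0.0
            out[:, pi, 0, 0] = m[:, 0]
            out[:, pi, 1, 1] = m[:, 1]
        elif ci_a is not None and ci_a == ci_b:
            cidx, bits, Wn = comp_data(ci_a)
            ja = int(np.where(cidx == ca)[0][0])
            jb = int(np.where(cidx == cb)[0][0])
            for aa in (0, 1):
                for bb in (0, 1):
                    mask = (bits[:, ja] == aa) & (bits[:, jb] == bb)
                    out[:, pi, aa, bb] = Wn[:, mask].sum(axis=1)
        else:
            ma, mb = marginal(ca), marginal(cb)
            out[:, pi] = ma[:, :, None] * mb[:, None, :]
    return out


# ---------------------------------------------------------------------------
# IBDGraphSet: K realizations of partitions along a grid, change-point coded
# ---------------------------------------------------------------------------


class IBDGraphSet:
    """K realizations of location-specific IBD partitions on a marker grid.

    ``realizations[k]`` is a list of ``(start_index, labels)`` change-points
    with strictly increasing start indices beginning at 0; the partition at
    grid index ``i`` is the one of the last change-point with
    ``start_index <= i``. Labels are int32 arrays over the slots of
    ``individuals`` (paternal then maternal per individual).
    """

    def __init__(self, individuals: Sequence[str], positions_cm,
                 realizations: list[list[tuple[int, np.ndarray]]]):
        self.individuals = [str(i) for i in individuals]
        self.positions_cm = np.asarray(positions_cm, dtype=float)
        self.realizations = realizations
        if not realizations:
            raise ValueError("an IBDGraphSet needs at least one realization")
        ns = 2 * len(self.individuals)
        for k, cps in enumerate(realizations):
            if not cps or cps[0][0] != 0:
                raise ValueError(f"realization {k} must start with a change-point at 0")
            last = -1
            for start, labels in cps:
                if start <= last or start >= self.positions_cm.size:
                    raise ValueError(f"realization {k}: bad change-point index {start}")
                if np.asarray(labels).size != ns:
                    raise ValueError(f"realization {k}: label vector of wrong length")
                last = start

    # -- accessors ---------------------------------------------------------

    @property
    def K(self) -> int:
        return len(self.realizations)

    @property
    def n_positions(self) -> int:
        return self.positions_cm.size

    @property
    def n_slots(self) -> int:
        return 2 * len(self.individuals)

    def slot_index(self, iid: str, slot: int) -> int:
        return 2 * self.individuals.index(str(iid)) + slot

    def labels_at(self, k: int, pos_index: int) -> np.ndarray:
        """Partition labels of realization ``k`` at grid index ``pos_index``."""
        cps = self.realizations[k]
        j = bisect.bisect_right([s for s, _ in cps], pos_index) - 1
        return cps[j][1]

    def dense(self, k: int) -> np.ndarray:
        """Expand realization ``k`` to an ``(L, 2 n)`` label array."""
        out = np.empty((self.n_positions, self.n_slots), dtype=np.int32)
        cps = self.realizations[k]
        for i, (start, labels) in enumerate(cps):
            end = cps[i + 1][0] if i + 1 < len(cps) else self.n_positions
            out[start:end] = labels
        return out

    @staticmethod
    def from_dense(individuals, positions_cm, dense_list) -> "IBDGraphSet":
        """Build from per-position label arrays, keeping a change-point only
        where the induced set-partition (not the raw labels) changes."""
        reals = []
        for dense in dense_list:
            dense = np.asarray(dense)
            cps: list[tuple[int, np.ndarray]] = []
            prev_key = None
            for i in range(dense.shape[0]):
                canon = canonical_labels(dense[i])
                key = canon.tobytes()
                if key != prev_key:
                    cps.append((i, canon))
                    prev_key = key
            reals.append(cps)
        return IBDGraphSet(individuals, positions_cm, reals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IBDGraphSet):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and np.array_equal(self.positions_cm, other.positions_cm)
            and len(self.realizations) == len(other.realizations)
            and all(
                len(a) == len(b)
                and all(sa == sb and np.array_equal(la, lb)
                        for (sa, la), (sb, lb) in zip(a, b))
                for a, b in zip(self.realizations, other.realizations)
            )
        )


def write_graphs(path, gset: IBDGraphSet) -> None:
    """Write the compact IBD-graph text format.

    Header: ``#individuals:``, ``#positions_cM:``, ``#realizations:``; then
    per realization a ``R k`` line followed by ``C <1-based position index>
    <label per slot>`` change-point lines (slots in header order, paternal
    before maternal).
    """
    with open(path, "w") as fh:
        fh.write("#individuals: " + " ".join(gset.individuals) + "\n")
        fh.write("#positions_cM: " + " ".join(repr(float(p)) for p in gset.positions_cm) + "\n")
        fh.write(f"#realizations: {gset.K}\n")
        for k, cps in enumerate(gset.realizations):
            fh.write(f"R {k + 1}\n")
            for start, labels in cps:
                fh.write(f"C {start + 1} " + " ".join(str(int(x)) for x in labels) + "\n")


def read_graphs(path) -> IBDGraphSet:
    """Read the compact IBD-graph format written by :func:`write_graphs`."""
    individuals: list[str] | None = None
    positions = None
    K = None
    reals: list[list[tuple[int, np.ndarray]]] = []
    current: list[tuple[int, np.ndarray]] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#individuals:"):
                individuals = line.split(":", 1)[1].split()
            elif line.startswith("#positions_cM:"):
                positions = np.array([float(x) for x in line.split(":", 1)[1].split()])
            elif line.startswith("#realizations:"):
                K = int(line.split(":", 1)[1])
            elif line.startswith("#"):
                continue
            elif line.startswith("R "):
                if current is not None:
                    reals.append(current)
                current = []
            elif line.startswith("C "):
                if current is None or individuals is None:
                    raise ValueError(f"{path}:{lineno}: change-point before 'R' header")
                parts = line.split()
                labels = np.array([int(x) for x in parts[2:]], dtype=np.int32)
                if labels.size != 2 * len(individuals):
                    raise ValueError(
                        f"{path}:{lineno}: expected {2 * len(individuals)} labels, "
                        f"got {labels.size}"
                    )
                current.append((int(parts[1]) - 1, labels))
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized line {line[:40]!r}")
    if current is not None:
        reals.append(current)
    if individuals is None or positions is None or K is None:
        raise ValueError(f"{path}: missing header line(s)")
    if len(reals) != K:
        raise ValueError(f"{path}: header announces {K} realizations, found {len(reals)}")
    return IBDGraphSet(individuals, positions, reals)


def nearest_positions(grid_cm, query_cm) -> np.ndarray:
    """Index of the nearest grid position for each query (ties -> lower)."""
    grid = np.asarray(grid_cm, dtype=float)
    q = np.atleast_1d(np.asarray(query_cm, dtype=float))
    right = np.searchsorted(grid, q)
    left = np.clip(right - 1, 0, grid.size - 1)
    right = np.clip(right, 0, grid.size - 1)
    choose_right = np.abs(grid[right] - q) < np.abs(q - grid[left])
    return np.where(choose_right, right, left)
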