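"""Pedigree structures, genetic maps, and prior (gene-drop) IBD simulation.

Conventions used throughout the package:

* haplotype **slot 0 is paternal, slot 1 is maternal** for every individual;
* analyses are autosomal — sex is read from pedigree files but plays no role
  in transmission;
* a *founder genome label* (FGL) identifies one founder haplotype; the IBD
  state of the sample at a genomic position is the partition of all haplotype
  slots into FGL classes;
* an *inheritance vector* (IV) holds one bit per meiosis (0 = grandpaternal,
  1 = grandmaternal); the meiosis order is deterministic: children in
  topological order, the paternal meiosis before the maternal one, so the
  same pedigree file always yields the same bit indexing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Member",
    "Pedigree",
    "PedigreeError",
    "GeneticMap",
    "read_pedigree",
    "read_pedigrees",
    "write_pedigree",
    "read_map",
    "write_map",
    "haldane_theta",
    "haldane_distance",
    "gene_drop",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree definition."""


@dataclass(frozen=True)
class Member:
    """One pedigree member. ``father``/``mother`` are ``None`` for founders."""

    iid: str
    father: str | None
    mother: str | None
    sex: int = 0


class Pedigree:
    """A validated pedigree with a deterministic meiosis ordering.

    Parameters
    ----------
    ped_id:
        Namespace tag for the pedigree (the family column of a PED file).
    members:
        Iterable of :class:`Member`. Every non-founder must name both
        parents and both parents must themselves be members; the
        parent–child graph must be acyclic.
    """

    def __init__(self, ped_id: str, members: Iterable[Member]):
        self.ped_id = str(ped_id)
        self.members: list[Member] = list(members)
        if not self.members:
            raise PedigreeError(f"pedigree {ped_id!r} has no members")
        self._index = {m.iid: i for i, m in enumerate(self.members)}
        if len(self._index) != len(self.members):
            raise PedigreeError(f"pedigree {ped_id!r} has duplicate individual ids")
        self._validate()
        self.founders = [m.iid for m in self.members if m.father is None]
        self.non_founders = [m.iid for m in self.members if m.father is not None]
        self._topo = self._topological_children()
        #: ordered meiosis list: (child-id, slot) with slot 0 = paternal
        self.meioses: list[tuple[str, int]] = [
            (child, slot) for child in self._topo for slot in (0, 1)
        ]
        self.meiosis_index = {cs: i for i, cs in enumerate(self.meioses)}

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.members)

    @property
    def individuals(self) -> list[str]:
        return [m.iid for m in self.members]

    @property
    def n_meioses(self) -> int:
        return len(self.meioses)

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    def member(self, iid: str) -> Member:
        return self.members[self._index[iid]]

    def index(self, iid: str) -> int:
        return self._index[iid]

    def slot_index(self, iid: str, slot: int) -> int:
        """Global slot index within this pedigree: ``2 * member_index + slot``."""
        if slot not in (0, 1):
            raise ValueError("slot must be 0 (paternal) or 1 (maternal)")
        return 2 * self._index[iid] + slot

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        for m in self.members:
            has_f, has_m = m.father is not None, m.mother is not None
            if has_f != has_m:
                raise PedigreeError(
                    f"individual {m.iid!r} in pedigree {self.ped_id!r} lists only "
                    "one parent; founders must have zero parents, others two"
                )
            for p in (m.father, m.mother):
                if p is not None and p not in self._index:
                    raise PedigreeError(
                        f"parent {p!r} of individual {m.iid!r} is missing from "
                        f"pedigree {self.ped_id!r}"
                    )

    def _topological_children(self) -> list[str]:
        """Kahn topological order of non-founders, tie-broken by file order."""
        n_parents_left = {}
        children_of: dict[str, list[str]] = {m.iid: [] for m in self.members}
        for m in self.members:
            if m.father is not None:
                n_parents_left[m.iid] = 2
                children_of[m.father].append(m.iid)
                children_of[m.mother].append(m.iid)
        order: list[str] = []
        ready = [m.iid for m in self.members if m.father is None]
        done = set(ready)
        # stable queue: founders in file order, then children as released
        queue = list(ready)
        while queue:
            nxt: list[str] = []
            for iid in queue:
                for child in children_of[iid]:
                    n_parents_left[child] -= 1
            # release in file order for determinism
            for m in self.members:
                if m.father is not None and m.iid not in done and n_parents_left[m.iid] == 0:
                    order.append(m.iid)
                    done.add(m.iid)
                    nxt.append(m.iid)
            queue = nxt
        if len(order) != len(self.members) - len([m for m in self.members if m.father is None]):
            bad = [m.iid for m in self.members if m.iid not in done]
            raise PedigreeError(
                f"pedigree {self.ped_id!r} contains a parent-child cycle involving {bad}"
            )
        return order

    # -- structure ---------------------------------------------------------

    def components(self) -> list["Pedigree"]:
        """Connected components as sub-pedigrees (deterministic order).

        Individuals are connected through parent-child links. Each component
        is returned as its own :class:`Pedigree` sharing ``ped_id``; member
        and meiosis ordering inside each component follows the original file
        order, so conditional samplers factorize cleanly over components.
        """
        parent = {m.iid: m.iid for m in self.members}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: str, b: str) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        for m in self.members:
            if m.father is not None:
                union(m.iid, m.father)
                union(m.iid, m.mother)
        groups: dict[str, list[Member]] = {}
        order: list[str] = []
        for m in self.members:
            r = find(m.iid)
            if r not in groups:
                groups[r] = []
                order.append(r)
            groups[r].append(m)
        return [Pedigree(self.ped_id, groups[r]) for r in order]


# ---------------------------------------------------------------------------
# PED file I/O
# ---------------------------------------------------------------------------


def _ped_rows(path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise PedigreeError(
                    f"{path}:{lineno}: expected 5 columns "
                    "(family id father mother sex), got "
                    f"{len(parts)}"
                )
            rows.append(parts[:5])
    return rows


def read_pedigrees(path) -> list[Pedigree]:
    """Read a whitespace-delimited PED-style file into pedigrees.

    Columns: family, id, father, mother, sex; ``0`` denotes a missing
    parent; ``#`` starts a comment; an optional header line is skipped if
    its second column is literally ``id``.
    """
    rows = _ped_rows(path)
    if rows and rows[0][1].lower() == "id":
        rows = rows[1:]
    fams: dict[str, list[Member]] = {}
    order: list[str] = []
    for fam, iid, fa, mo, sex in rows:
        if fam not in fams:
            fams[fam] = []
            order.append(fam)
        fams[fam].append(
            Member(
                iid,
                None if fa == "0" else fa,
                None if mo == "0" else mo,
                int(sex) if sex.isdigit() else 0,
            )
        )
    return [Pedigree(fam, fams[fam]) for fam in order]


def read_pedigree(path, family: str | None = None) -> Pedigree:
    """Read a single pedigree; ``family`` selects one when the file has several."""
    peds = read_pedigrees(path)
    if family is not None:
        for p in peds:
            if p.ped_id == family:
                return p
        raise PedigreeError(f"family {family!r} not found in {path}")
    if len(peds) != 1:
        raise PedigreeError(
            f"{path} contains {len(peds)} families; pass family= to choose one"
        )
    return peds[0]


def write_pedigree(path, peds: Sequence[Pedigree]) -> None:
    with open(path, "w") as fh:
        fh.write("# family id father mother sex\n")
        for ped in peds:
            for m in ped.members:
                fh.write(
                    f"{ped.ped_id} {m.iid} {m.father or 0} {m.mother or 0} {m.sex}\n"
                )


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------


def haldane_theta(d):
    """Haldane map function: recombination fraction for a distance in cM.

    theta = (1 - exp(-2 d / 100)) / 2, so theta -> 0.5 as d -> infinity.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * -np.expm1(-2.0 * d / 100.0)
    return float(out) if out.ndim == 0 else out

def haldane_distance(theta):
    """Inverse Haldane map: distance in cM for a recombination fraction."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = -50.0 * np.log1p(-2.0 * theta)
    return float(out) if out.ndim == 0 else out


class GeneticMap:
    """Ordered marker map with bp and cM positions (Haldane assumed).

    ``thetas[i]`` is the recombination fraction between markers ``i`` and
    ``i + 1``.
    """

    def __init__(self, markers: Sequence[str], positions_cm, positions_bp=None, chrom="1"):
        self.markers = list(map(str, markers))
        self.positions_cm = np.asarray(positions_cm, dtype=float)
        if positions_bp is None:
            positions_bp = np.round(self.positions_cm * 1e6).astype(np.int64)
        self.positions_bp = np.asarray(positions_bp, dtype=np.int64)
        self.chrom = str(chrom)
        if len(self.markers) != len(self.positions_cm):
            raise ValueError("marker names and cM positions differ in length")
        if np.any(np.diff(self.positions_cm) <= 0) or np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("map positions must be strictly increasing in cM and bp")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def thetas(self) -> np.ndarray:
        return haldane_theta(np.diff(self.positions_cm))


def read_map(path) -> GeneticMap:
    """Read a MAP-style file with columns chrom, marker-id, cM, bp."""
    chroms, names, cms, bps = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected chrom marker cM bp")
            if lineno == 1 and not _is_number(parts[2]):
                continue  # header
            chroms.append(parts[0])
            names.append(parts[1])
            cms.append(float(parts[2]))
            bps.append(int(float(parts[3])))
    return GeneticMap(names, cms, bps, chrom=chroms[0] if chroms else "1")


def write_map(path, gmap: GeneticMap) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom marker cM bp\n")
        for name, cm, bp in zip(gmap.markers, gmap.positions_cm, gmap.positions_bp):
            fh.write(f"{gmap.chrom} {name} {float(cm)!r} {int(bp)}\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Gene dropping (prior IBD)
# ---------------------------------------------------------------------------


def gene_drop(ped: Pedigree, positions_cm, seed=None, rng=None) -> np.ndarray:
    """Simulate one unconditional IBD realization over a marker grid.

    Founders carry fixed distinct FGLs (founder ``j`` contributes labels
    ``2 j`` and ``2 j + 1``) at every position; each meiosis follows a
    two-state Markov chain along the chromosome with switch probability
    given by the Haldane map function for each inter-marker interval.

    Returns an ``(L, 2 n)`` int32 array of FGL labels, slot columns ordered
    ``(member 0 paternal, member 0 maternal, member 1 paternal, ...)``.
    """
    positions_cm = np.atleast_1d(np.asarray(positions_cm, dtype=float))
    L = positions_cm.size
    if L == 0:
        raise ValueError("positions_cm must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    thetas = haldane_theta(np.diff(positions_cm)) if L > 1 else np.empty(0)
    n = len(ped)
    labels = np.empty((L, 2 * n), dtype=np.int32)
    founder_rank = {iid: r for r, iid in enumerate(ped.founders)}
    for iid in ped.founders:
        j = founder_rank[iid]
        labels[:, ped.slot_index(iid, 0)] = 2 * j
        labels[:, ped.slot_index(iid, 1)] = 2 * j + 1
    bits = sample_meiosis_bits(ped.n_meioses, thetas, rng)  # (L, m)
    for mi, (child, slot) in enumerate(ped.meioses):
        mem = ped.member(child)
        parent = mem.father if slot == 0 else mem.mother
        pat = labels[:, ped.slot_index(parent, 0)]
        mat = labels[:, ped.slot_index(parent, 1)]
        b = bits[:, mi]
        labels[:, ped.slot_index(child, slot)] = np.where(b == 0, pat, mat)
    return labels


def sample_meiosis_bits(n_meioses: int, thetas, rng) -> np.ndarray:
    """Sample ``(L, m)`` grandparental-origin bits: independent Markov chains
    with per-interval switch probabilities ``thetas`` (length ``L - 1``)."""
    thetas = np.asarray(thetas, dtype=float)
    L = thetas.size + 1
    if n_meioses == 0:
        return np.zeros((L, 0), dtype=np.int8)
    start = rng.integers(0, 2, size=n_meioses, dtype=np.int8)
    if L == 1:
        return start[None, :]
    switches = (rng.random((L - 1, n_meioses)) < thetas[:, None]).astype(np.int8)
    cum = np.zeros((L, n_meioses), dtype=np.int8)
    cum[1:] = np.cumsum(switches, axis=0) % 2
    return (start[None, :] ^ cum).astype(np.int8)
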