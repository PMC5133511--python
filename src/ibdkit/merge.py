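"""Merging pedigree IBD graphs with between-pedigree (bridge) IBD graphs.

The merge takes per-pedigree :class:`~ibdkit.graphs.IBDGraphSet` objects
(disjoint slot namespaces) plus a bridge set realized jointly on a subset
of those individuals — typically the output of :func:`ibdkit.cryptic.stitch`
— and produces combined graphs on the union of individuals: at every grid
position and realization the output partition is the union-find closure of
the pedigree partitions together with the slot equivalences asserted by
the bridge partition. Pedigree-internal sharing is never removed; the
result is a coarsening of the disjoint union. Realization k of every input
is paired with realization k.

Bridge haplotypes carry no inherent phase relative to pedigree slots
(founder phase is unidentifiable in both samplers), so each bridge
individual needs a per-realization choice between the identity and the
swapped slot correspondence. :func:`allele_align` scores both against the
pedigree-side posterior class-allele frequencies at the sparse markers,
using the bridge realization's sampled haplotype alleles; a coin-flip
(identity) alignment would be wrong for half the individuals per
realization and wash out the cross-pedigree signal.
"""

from __future__ import annotations

import numpy as np

from .genotypes import PanelData
from .graphs import IBDGraphSet, canonical_labels, class_allele_marginals, \
    nearest_positions
from .cryptic import StitchResult

__all__ = ["merge_graphs", "allele_align", "identity_alignment"]


def identity_alignment(bridge: IBDGraphSet) -> np.ndarray:
    """All-identity slot correspondence: (K, n_bridge) zeros."""
    return np.zeros((bridge.K, len(bridge.individuals)), dtype=np.int8)


def allele_align(ped_sets: list[IBDGraphSet], stitch_result: StitchResult,
                 sparse_panel: PanelData, eps: float | None = None) -> np.ndarray:
    """Per-individual, per-realization bridge-phase alignment (0 = identity,
    1 = swap), chosen by allele agreement at the sparse markers.

    For bridge individual i and realization k, the pedigree realization
    determines (up to founder phase) which FGL class each of i's slots
    belongs to; the posterior alternate-allele frequency of those classes
    given the sparse genotypes is compared with the alleles of the bridge
    realization's sampled haplotypes at the same markers, and the
    correspondence with the larger log-agreement wins (ties -> identity).
    Sparse markers must be present in the stitched (dense) panel.
    """
    bridge = stitch_result.graphs
    eps = sparse_panel.eps if eps is None else eps
    # locate each bridge individual's pedigree set and slot columns
    homes: list[tuple[int, int]] = []
    for iid in bridge.individuals:
        hit = None
        for si, gs in enumerate(ped_sets):
            if iid in gs.individuals:
                hit = (si, gs.individuals.index(iid))
                break
        if hit is None:
            raise ValueError(f"bridge individual {iid!r} absent from all pedigrees")
        homes.append(hit)
    # sparse markers inside the dense panel of the stitch
    dense_idx = []
    sparse_idx = []
    dense_pos = {m: j for j, m in enumerate(_dense_markers(stitch_result))}
    for j, m in enumerate(sparse_panel.markers):
        if m in dense_pos:
            sparse_idx.append(j)
            dense_idx.append(dense_pos[m])
    if not sparse_idx:
        raise ValueError(
            "no sparse markers found in the stitched panel; allele alignment "
            "needs the sparse panel to be a subset of the dense panel"
        )
    sparse_idx = np.array(sparse_idx)
    dense_idx = np.array(dense_idx)
    freqs = sparse_panel.freqs
    K = bridge.K
    align = np.zeros((K, len(bridge.individuals)), dtype=np.int8)
    # pedigree-side genotype matrices aligned to each set's individuals
    ped_G = []
    for gs in ped_sets:
        cols = {iid: c for c, iid in enumerate(sparse_panel.individuals)}
        G = np.full((sparse_panel.n_markers, len(gs.individuals)), -1, dtype=np.int8)
        for c, iid in enumerate(gs.individuals):
            if iid in cols:
                G[:, c] = sparse_panel.genotypes[:, cols[iid]]
        ped_G.append(G)
    # class-allele posteriors cached per *component* partition (the family
    # unit containing the bridge individual), not per full-pedigree labels
    marg_cache: dict[tuple, tuple[np.ndarray, dict[int, int]]] = {}

    def slot_marginals(si: int, labels: np.ndarray, col: int):
        """(2, L_sparse) P(alt) for the two slots of individual ``col``."""
        n = labels.size // 2
        pair = labels.reshape(n, 2)
        comp = _component_individuals(pair, col)
        sub = canonical_labels(labels, np.stack([2 * comp, 2 * comp + 1], 1).ravel())
        key = (si, comp.tobytes(), sub.tobytes())
        if key not in marg_cache:
            marg, cids = class_allele_marginals(sub, ped_G[si][:, comp], freqs, eps)
            marg_cache[key] = (marg, {int(c): j for j, c in enumerate(cids)})
        marg, colmap = marg_cache[key]
        ci = int(np.where(comp == col)[0][0])
        return np.stack([marg[:, colmap[int(sub[2 * ci])]],
                         marg[:, colmap[int(sub[2 * ci + 1])]]])

    for k in range(K):
        hap = stitch_result.haplotypes[k]  # (2 n_bridge, L_dense)
        for bi, iid in enumerate(bridge.individuals):
            si, col = homes[bi]
            gs = ped_sets[si]
            # pedigree-side P(alt) per sparse marker for slots 0 and 1
            p_slot = np.empty((2, sparse_idx.size))
            cps = gs.realizations[k]
            for ci, (start, labels) in enumerate(cps):
                end = cps[ci + 1][0] if ci + 1 < len(cps) else gs.n_positions
                sel = (sparse_idx >= start) & (sparse_idx < end)
                if not np.any(sel):
                    continue
                m2 = slot_marginals(si, np.asarray(labels), col)
                p_slot[:, sel] = m2[:, sparse_idx[sel]]
            p_slot = np.clip(p_slot, 1e-6, 1 - 1e-6)
            h = hap[2 * bi:2 * bi + 2, dense_idx].astype(float)  # (2, M)
            def score(h0, h1):
                return float(np.sum(np.log(h0 * p_slot[0] + (1 - h0) * (1 - p_slot[0])))
                             + np.sum(np.log(h1 * p_slot[1] + (1 - h1) * (1 - p_slot[1]))))
            align[k, bi] = 0 if score(h[0], h[1]) >= score(h[1], h[0]) else 1
    return align


def _component_individuals(pair_classes: np.ndarray, col: int) -> np.ndarray:
    """Indices of individuals whose classes connect to individual ``col``."""
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
    root = find(int(pair_classes[col][0]))
    return np.array([i for i in range(pair_classes.shape[0])
                     if find(int(pair_classes[i][0])) == root])


def _dense_markers(stitch_result: StitchResult) -> list[str]:
    markers = getattr(stitch_result, "markers", None)
    if markers:
        return markers
    # fall back to positions as identifiers
    return [repr(float(p)) for p in stitch_result.graphs.positions_cm]


def merge_graphs(ped_sets: list[IBDGraphSet], bridge: IBDGraphSet,
                 slot_alignment: np.ndarray | None = None,
                 groups: list[list[str]] | None = None) -> IBDGraphSet:
    """Merge per-pedigree IBD graphs with a bridge graph set.

    Parameters
    ----------
    ped_sets:
        Per-pedigree graph sets sharing K and a common position grid.
    bridge:
        Joint graphs on the bridge individuals, any position grid (mapped
        to the pedigree grid by nearest position, ties toward the lower
        position). Every bridge individual must belong to some pedigree.
    slot_alignment:
        ``(K, n_bridge)`` array, 0 = identity, 1 = swapped slot
        correspondence per individual and realization; default identity.
        Use :func:`allele_align` for the data-driven choice.
    groups:
        Optional list of bridge-individual groups; equivalences are applied
        only within a group (the merged-in-groups option). Default: all
        bridge individuals in one group.

    Returns the merged :class:`IBDGraphSet` on the union of individuals, a
    coarsening of the disjoint union at every position and realization.
    """
    if not ped_sets:
        raise ValueError("need at least one pedigree graph set")
    K = ped_sets[0].K
    grid = ped_sets[0].positions_cm
    for gs in ped_sets[1:]:
        if gs.K != K or not np.array_equal(gs.positions_cm, grid):
            raise ValueError("pedigree graph sets must share K and position grid")
    if bridge.K != K:
        raise ValueError(f"bridge has K={bridge.K}, pedigrees have K={K}")
    if slot_alignment is None:
        slot_alignment = np.zeros((K, len(bridge.individuals)), dtype=np.int8)
    slot_alignment = np.asarray(slot_alignment)
    if slot_alignment.shape != (K, len(bridge.individuals)):
        raise ValueError("slot_alignment must have shape (K, n_bridge)")
    group_of = {}
    if groups is None:
        for iid in bridge.individuals:
            group_of[iid] = 0
    else:
        for gi, grp in enumerate(groups):
            for iid in grp:
                group_of[iid] = gi
    # global slot layout: pedigree sets concatenated
    individuals: list[str] = []
    offsets: list[int] = []
    for gs in ped_sets:
        offsets.append(2 * len(individuals))
        individuals.extend(gs.individuals)
    home: dict[str, tuple[int, int]] = {}
    for si, gs in enumerate(ped_sets):
        for c, iid in enumerate(gs.individuals):
            home[iid] = (si, c)
    for iid in bridge.individuals:
        if iid not in home:
            raise ValueError(f"bridge individual {iid!r} absent from all pedigrees")
    # bridge grid index per pedigree-grid position
    b_near = nearest_positions(bridge.positions_cm, grid)
    n_slots = 2 * len(individuals)
    L = grid.size
    realizations = []
    for k in range(K):
        events = set()
        for gs in ped_sets:
            events.update(start for start, _ in gs.realizations[k])
        # bridge change-points mapped onto the grid: grid positions where the
        # down-sampled bridge partition may change
        b_starts = [start for start, _ in bridge.realizations[k]]
        prev = None
        for i in range(L):
            j = int(np.searchsorted(b_starts, b_near[i], side="right")) - 1
            if prev is None or j != prev:
                events.add(i)
            prev = j
        cps: list[tuple[int, np.ndarray]] = []
        prev_key = None
        for i in sorted(events):
            labels = _merged_labels(ped_sets, bridge, k, i, int(b_near[i]),
                                    offsets, home, slot_alignment[k], group_of,
                                    n_slots)
            key = labels.tobytes()
            if key != prev_key:
                cps.append((i, labels))
                prev_key = key
        realizations.append(cps)
    return IBDGraphSet(individuals, grid, realizations)


def _merged_labels(ped_sets, bridge, k, grid_i, bridge_i, offsets, home,
                   align_k, group_of, n_slots) -> np.ndarray:
    base = np.empty(n_slots, dtype=np.int64)
    label_off = 0
    for si, gs in enumerate(ped_sets):
        lab = np.asarray(gs.labels_at(k, grid_i), dtype=np.int64)
        base[offsets[si]:offsets[si] + lab.size] = lab + label_off
        label_off += int(lab.max()) + 1
    blab = np.asarray(bridge.labels_at(k, bridge_i))
    # group bridge slots by (group, bridge class); union their pedigree classes
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    buckets: dict[tuple[int, int], list[int]] = {}
    for bi, iid in enumerate(bridge.individuals):
        si, col = home[iid]
        swap = int(align_k[bi])
        for s in (0, 1):
            ped_slot = offsets[si] + 2 * col + (s ^ swap)
            buckets.setdefault(
                (group_of[iid], int(blab[2 * bi + s])), []
            ).append(ped_slot)
    for slots in buckets.values():
        for a, b in zip(slots, slots[1:]):
            ra, rb = find(int(base[a])), find(int(base[b]))
            if ra != rb:
                parent[rb] = ra
    merged = base.copy()
    for lab in list(parent):
        root = find(lab)
        if root != lab:
            merged[base == lab] = root
    return canonical_labels(merged)
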