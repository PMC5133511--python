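"""Synthetic multi-pedigree datasets with planted cryptic relatedness.

The generator emulates a workshop-style study: several extended pedigrees
genotyped on a sparse, well-spaced, linkage-equilibrium marker panel; a
dense panel (MAF above a floor) on a subset of individuals; a biallelic
QTL driving a quantitative trait with many simulated replicates; and a
set of *bridge* founders in different pedigrees who share a hidden founder
haplotype segment — relatedness that exists in the genomes but not in the
recorded pedigree files.

Pedigrees are built from three-generation family units (a grandparental
couple, their children, one child married to a founder spouse, and
grandchildren). Units are connected components below the exact-IV-sampling
meiosis cap, so every stage of the toolkit runs on the output without
MCMC. Cryptic relatedness is planted by giving designated marry-in
founders ("bridge" individuals) a common hidden FGL on a configured
interval of their paternal slot; gene drop over each pedigree then
propagates the shared segment to descendants, keeping cross-pedigree IBD
segmental, transitive, and map-consistent. The hidden FGL carries the
trait-increasing allele at the QTL, which is what makes between-pedigree
IBD informative for mapping.

Marker genotypes are emitted from the true FGL alleles with a symmetric
per-allele error; sparse markers are simulated in linkage equilibrium
(independent frequencies) and are a subset of the dense panel, so the
panels can be aligned by marker name downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import PanelData, write_genotypes_tabular, read_genotypes_tabular, \
    write_frequencies, read_frequencies
from .graphs import IBDGraphSet, read_graphs, write_graphs
from .lod import QTLModel
from .pedigree import (GeneticMap, Member, Pedigree, read_pedigrees,
                       sample_meiosis_bits, write_pedigree, write_map, read_map,
                       haldane_theta)

__all__ = ["UnitSpec", "CrypticSpec", "SparseSpec", "DenseSpec", "QTLSpec",
           "SimulationConfig", "TruthRecord", "SimDataset", "simulate",
           "mini_config", "paper_emulation_config",
           "trait_variance_explained", "additive_displacement_for_ve"]


@dataclass
class UnitSpec:
    """Shape of one three-generation family unit."""

    n_children: int = 2       # children of the grandparental couple
    n_grandchildren: int = 3  # children of the first child and a founder spouse

    @property
    def n_members(self) -> int:
        return 3 + self.n_children + self.n_grandchildren

    @property
    def n_meioses(self) -> int:
        return 2 * (self.n_children + self.n_grandchildren)


@dataclass
class CrypticSpec:
    """Planted cross-pedigree sharing among bridge founders.

    ``groups`` lists pedigree indices per sharing group; within a group,
    the first ``per_pedigree`` marry-in founders of each member pedigree
    share one hidden FGL on the configured interval (``length_cm=None``
    means the whole chromosome).
    """

    per_pedigree: int = 0
    groups: list = field(default_factory=list)
    center_cm: float = 0.0
    length_cm: float | None = None


@dataclass
class SparseSpec:
    n_markers: int = 60
    spacing_cm: float = 1.5
    freq_range: tuple[float, float] = (0.2, 0.8)


@dataclass
class DenseSpec:
    n_markers: int = 180          # includes the sparse markers
    maf_floor: float = 0.05


@dataclass
class QTLSpec:
    position_cm: float = 45.0
    q: float = 0.1
    mu: tuple[float, float, float] = (0.0, 1.0, 2.0)
    sigma2: float = 1.0

    def model(self) -> QTLModel:
        return QTLModel(self.q, self.mu, self.sigma2)


@dataclass
class SimulationConfig:
    n_pedigrees: int = 3
    units_per_pedigree: int = 2
    unit: UnitSpec = field(default_factory=UnitSpec)
    cryptic: CrypticSpec = field(default_factory=CrypticSpec)
    sparse: SparseSpec = field(default_factory=SparseSpec)
    dense: DenseSpec = field(default_factory=DenseSpec)
    qtl: QTLSpec = field(default_factory=QTLSpec)
    n_trait_replicates: int = 20
    dense_typed_fraction: float = 0.0  # besides bridge individuals
    genotype_error: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.dense.maf_floor < 0.5:
            raise ValueError("dense MAF floor must lie in (0, 0.5)")
        lo, hi = self.sparse.freq_range
        if not 0 < lo < hi < 1:
            raise ValueError("sparse frequency range must satisfy 0 < lo < hi < 1")
        if self.dense.n_markers < self.sparse.n_markers:
            raise ValueError("dense panel must contain the sparse markers")
        if self.cryptic.per_pedigree > self.units_per_pedigree:
            raise ValueError("more bridge founders than units per pedigree")
        span = self.sparse.spacing_cm * (self.sparse.n_markers - 1)
        if not 0 <= self.qtl.position_cm <= span:
            raise ValueError("QTL position outside the map")


# ---------------------------------------------------------------------------
# variance-explained calibration
# ---------------------------------------------------------------------------


def trait_variance_explained(qtl: QTLSpec | QTLModel) -> float:
    """Proportion of trait variance explained by the QTL under HWE."""
    q = qtl.q
    mu = np.asarray(qtl.mu, dtype=float)
    w = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    vg = float(w @ mu ** 2 - (w @ mu) ** 2)
    return vg / (vg + qtl.sigma2)


def additive_displacement_for_ve(q: float, target_ve: float,
                                 sigma2: float = 1.0) -> float:
    """Per-allele displacement a of an additive model mu = (0, a, 2a)
    achieving a target variance explained."""
    if not 0 < target_ve < 1:
        raise ValueError("target variance explained must lie in (0, 1)")
    vg = target_ve * sigma2 / (1 - target_ve)
    return float(np.sqrt(vg / (2 * q * (1 - q))))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def mini_config(seed: int = 0) -> SimulationConfig:
    """Seconds-scale dataset: 3 pedigrees x 2 units (54 individuals),
    60 sparse markers over ~88 cM, a chip-density dense panel (~0.25 cM
    spacing), and a planted one-group bridge of 6 founders sharing 20 cM
    around the 45 cM QTL (additive, variance explained 0.15)."""
    a = additive_displacement_for_ve(0.1, 0.15)
    return SimulationConfig(
        n_pedigrees=3, units_per_pedigree=2,
        unit=UnitSpec(n_children=3, n_grandchildren=3),
        cryptic=CrypticSpec(per_pedigree=2, groups=[[0, 1, 2]],
                            center_cm=45.0, length_cm=20.0),
        sparse=SparseSpec(n_markers=60, spacing_cm=1.5),
        dense=DenseSpec(n_markers=360, maf_floor=0.05),
        qtl=QTLSpec(position_cm=45.0, q=0.1, mu=(0.0, a, 2 * a), sigma2=1.0),
        n_trait_replicates=20, dense_typed_fraction=0.5,
        seed=seed,
    )


def paper_emulation_config(seed: int = 0) -> SimulationConfig:
    """Scaled emulation of the 7-pedigree IBD-mapping scenario.

    7 pedigrees of 9 family units (504 individuals); 351 sparse markers at
    0.64 cM spacing (linkage equilibrium); a dense panel of 702 markers
    (MAF > 0.05) containing the sparse panel; 21 bridge founders (3 per
    pedigree) in two sharing groups — pedigrees {0,1,2,3} and {4,5,6} —
    each group sharing one hidden 25 cM founder segment centred at 62.5 cM
    (so sharing spans 50-75 cM); an additive QTL at 69 cM; 200 trait
    replicates. The QTL's variance explained (0.22) is calibrated via
    :func:`trait_variance_explained` so that the unmerged per-pedigree
    analysis sits at the weak-signal level (peak replicate-averaged LOD
    around 1) while the merged graphs give a strong regional signal —
    the contrast the scenario exists to exhibit.
    """
    a = additive_displacement_for_ve(0.1, 0.22)
    return SimulationConfig(
        n_pedigrees=7, units_per_pedigree=9,
        unit=UnitSpec(n_children=2, n_grandchildren=3),
        cryptic=CrypticSpec(per_pedigree=3, groups=[[0, 1, 2, 3], [4, 5, 6]],
                            center_cm=62.5, length_cm=25.0),
        sparse=SparseSpec(n_markers=351, spacing_cm=0.64),
        dense=DenseSpec(n_markers=702, maf_floor=0.05),
        qtl=QTLSpec(position_cm=69.0, q=0.1, mu=(0.0, a, 2 * a), sigma2=1.0),
        n_trait_replicates=200, dense_typed_fraction=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    """Ground truth behind a simulated dataset."""

    graph: IBDGraphSet            # true IBD at the sparse positions, K=1
    qtl_genotypes: dict           # individual -> 0/1/2 at the QTL
    bridge_individuals: list
    groups: list                  # bridge ids per sharing group
    cryptic_pairs: list           # all within-group bridge pairs


@dataclass
class SimDataset:
    config: SimulationConfig
    pedigrees: list
    sparse_map: GeneticMap
    dense_map: GeneticMap
    sparse: PanelData             # all individuals
    dense: PanelData              # dense-typed individuals only
    dense_true: PanelData         # true dense genotypes, all individuals
    traits: pd.DataFrame
    qtl_model: QTLModel
    truth: TruthRecord

    # -- persistence -------------------------------------------------------

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_pedigree(out / "pedigree.ped", self.pedigrees)
        write_map(out / "sparse.map", self.sparse_map)
        write_map(out / "dense.map", self.dense_map)
        write_genotypes_tabular(out / "sparse_genotypes.tsv", self.sparse)
        write_genotypes_tabular(out / "dense_genotypes.tsv", self.dense)
        write_genotypes_tabular(out / "dense_true_genotypes.tsv", self.dense_true)
        write_frequencies(out / "sparse_freqs.tsv", self.sparse.markers,
                          self.sparse.freqs)
        write_frequencies(out / "dense_freqs.tsv", self.dense.markers,
                          self.dense.freqs)
        tr = self.traits.copy()
        tr.index.name = "individual"
        tr.to_csv(out / "traits.tsv", sep="\t", float_format="%.17g")
        self.qtl_model.to_yaml(out / "qtl_model.yaml")
        write_graphs(out / "truth_graphs.txt", self.truth.graph)
        meta = {
            "config": asdict(self.config),
            "qtl_genotypes": {k: int(v) for k, v in self.truth.qtl_genotypes.items()},
            "bridge_individuals": list(self.truth.bridge_individuals),
            "groups": [list(g) for g in self.truth.groups],
            "cryptic_pairs": [list(p) for p in self.truth.cryptic_pairs],
        }
        (out / "truth.json").write_text(json.dumps(meta, indent=1))

    @staticmethod
    def read(outdir) -> "SimDataset":
        out = Path(outdir)
        meta = json.loads((out / "truth.json").read_text())
        cfg_d = meta["config"]
        cfg = SimulationConfig(
            n_pedigrees=cfg_d["n_pedigrees"],
            units_per_pedigree=cfg_d["units_per_pedigree"],
            unit=UnitSpec(**cfg_d["unit"]),
            cryptic=CrypticSpec(**cfg_d["cryptic"]),
            sparse=SparseSpec(n_markers=cfg_d["sparse"]["n_markers"],
                              spacing_cm=cfg_d["sparse"]["spacing_cm"],
                              freq_range=tuple(cfg_d["sparse"]["freq_range"])),
            dense=DenseSpec(**cfg_d["dense"]),
            qtl=QTLSpec(position_cm=cfg_d["qtl"]["position_cm"], q=cfg_d["qtl"]["q"],
                        mu=tuple(cfg_d["qtl"]["mu"]), sigma2=cfg_d["qtl"]["sigma2"]),
            n_trait_replicates=cfg_d["n_trait_replicates"],
            dense_typed_fraction=cfg_d["dense_typed_fraction"],
            genotype_error=cfg_d["genotype_error"],
            seed=cfg_d["seed"],
        )
        peds = read_pedigrees(out / "pedigree.ped")
        smap = read_map(out / "sparse.map")
        dmap = read_map(out / "dense.map")
        sfr = read_frequencies(out / "sparse_freqs.tsv")
        dfr = read_frequencies(out / "dense_freqs.tsv")
        sparse = read_genotypes_tabular(out / "sparse_genotypes.tsv",
                                        positions_cm=dict(zip(smap.markers, smap.positions_cm)),
                                        freqs=sfr, eps=cfg.genotype_error)
        dense = read_genotypes_tabular(out / "dense_genotypes.tsv",
                                       positions_cm=dict(zip(dmap.markers, dmap.positions_cm)),
                                       freqs=dfr, eps=cfg.genotype_error)
        dense_true = read_genotypes_tabular(out / "dense_true_genotypes.tsv",
                                            positions_cm=dict(zip(dmap.markers, dmap.positions_cm)),
                                            freqs=dfr, eps=0.0)
        traits = pd.read_csv(out / "traits.tsv", sep="\t", index_col=0,
                             float_precision="round_trip")
        traits.index = traits.index.astype(str)
        qtl_model = QTLModel.from_yaml(out / "qtl_model.yaml")
        truth = TruthRecord(read_graphs(out / "truth_graphs.txt"),
                            meta["qtl_genotypes"], meta["bridge_individuals"],
                            meta["groups"], [tuple(p) for p in meta["cryptic_pairs"]])
        return SimDataset(cfg, peds, smap, dmap, sparse, dense, dense_true,
                          traits, qtl_model, truth)


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def _build_unit(ped_id: str, u: int, spec: UnitSpec) -> list[Member]:
    p = f"{ped_id}_U{u}"
    members = [Member(f"{p}_F", None, None, 1), Member(f"{p}_M", None, None, 2)]
    children = [f"{p}_C{i}" for i in range(1, spec.n_children + 1)]
    for i, c in enumerate(children):
        members.append(Member(c, f"{p}_F", f"{p}_M", 1 + i % 2))
    members.append(Member(f"{p}_S", None, None, 2))  # marry-in spouse (founder)
    for i in range(1, spec.n_grandchildren + 1):
        members.append(Member(f"{p}_G{i}", children[0], f"{p}_S", 1 + i % 2))
    return members


def simulate(config: SimulationConfig, seed: int | None = None) -> SimDataset:
    """Generate a complete dataset bundle from a configuration.

    All randomness flows from one master seed through named substreams
    (structure/genotypes/traits), so a config and seed fully determine the
    output.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_ibd, rng_geno, rng_trait = (np.random.default_rng(s) for s in ss.spawn(3))

    # maps: sparse grid, dense grid containing it, plus the QTL position
    sp = config.sparse
    sparse_pos = np.arange(sp.n_markers) * sp.spacing_cm
    sparse_names = [f"s{i + 1}" for i in range(sp.n_markers)]
    n_extra = config.dense.n_markers - sp.n_markers
    span = sparse_pos[-1]
    extra_pos = (np.arange(n_extra) + 0.5) * span / n_extra
    # nudge any extra marker that lands exactly on a sparse position
    hit = np.isin(extra_pos, sparse_pos)
    extra_pos[hit] += 1e-4 * sp.spacing_cm
    dense_pos = np.concatenate([sparse_pos, extra_pos])
    dense_names = sparse_names + [f"d{i + 1}" for i in range(n_extra)]
    order = np.argsort(dense_pos, kind="stable")
    dense_pos = dense_pos[order]
    dense_names = [dense_names[i] for i in order]
    if np.any(np.diff(dense_pos) <= 0):  # extremely unlikely collision
        raise ValueError("dense marker positions collide; adjust panel sizes")

    all_pos = np.concatenate([dense_pos, [config.qtl.position_cm]])
    grid = np.unique(all_pos)
    qtl_gi = int(np.searchsorted(grid, config.qtl.position_cm))
    dense_gi = np.searchsorted(grid, dense_pos)
    sparse_gi = np.searchsorted(grid, sparse_pos)

    # frequencies
    lo, hi = sp.freq_range
    sparse_fr = rng_geno.uniform(lo, hi, sp.n_markers)
    fl = config.dense.maf_floor
    extra_fr = rng_geno.uniform(fl, 1 - fl, n_extra)
    dense_fr = np.empty(config.dense.n_markers)
    name_to_dense = {m: i for i, m in enumerate(dense_names)}
    for nm, f in zip(sparse_names, sparse_fr):
        dense_fr[name_to_dense[nm]] = f
    for i in range(n_extra):
        dense_fr[name_to_dense[f"d{i + 1}"]] = extra_fr[i]
    grid_fr = np.empty(grid.size)
    grid_fr[dense_gi] = dense_fr
    grid_fr[qtl_gi] = config.qtl.q

    # pedigrees
    peds = [
        Pedigree(f"P{p + 1}", [m for u in range(1, config.units_per_pedigree + 1)
                               for m in _build_unit(f"P{p + 1}", u, config.unit)])
        for p in range(config.n_pedigrees)
    ]
    all_inds = [iid for ped in peds for iid in ped.individuals]

    # bridge founders: the marry-in spouses of the first units of each pedigree
    bridge_by_group: list[list[str]] = []
    used_groups = config.cryptic.groups if config.cryptic.per_pedigree else []
    for grp in used_groups:
        ids = [f"P{p + 1}_U{u}_S" for p in grp
               for u in range(1, config.cryptic.per_pedigree + 1)]
        bridge_by_group.append(ids)
    bridge_ids = [i for g in bridge_by_group for i in g]

    # hidden-segment mask on the grid
    if config.cryptic.length_cm is None:
        seg_mask = np.ones(grid.size, dtype=bool)
    else:
        half = config.cryptic.length_cm / 2.0
        seg_mask = (grid >= config.cryptic.center_cm - half) & \
                   (grid <= config.cryptic.center_cm + half)

    # global FGL numbering: per-pedigree founders, then one hidden FGL per group
    n_founders_total = sum(p.n_founders for p in peds)
    hidden_fgl = {g: 2 * n_founders_total + gi
                  for gi, g in enumerate(range(len(bridge_by_group)))}
    group_of_bridge = {iid: gi for gi, ids in enumerate(bridge_by_group)
                       for iid in ids}

    # gene drop per pedigree with hidden founder segments
    L = grid.size
    truth_labels = np.empty((L, 2 * len(all_inds)), dtype=np.int32)
    col_of = {iid: i for i, iid in enumerate(all_inds)}
    fgl_offset = 0
    for ped in peds:
        lab = np.empty((L, 2 * len(ped)), dtype=np.int32)
        founder_rank = {iid: r for r, iid in enumerate(ped.founders)}
        for iid in ped.founders:
            j = founder_rank[iid]
            lab[:, ped.slot_index(iid, 0)] = fgl_offset + 2 * j
            lab[:, ped.slot_index(iid, 1)] = fgl_offset + 2 * j + 1
            if iid in group_of_bridge:
                gfgl = hidden_fgl[group_of_bridge[iid]]
                lab[seg_mask, ped.slot_index(iid, 0)] = gfgl
        thetas = haldane_theta(np.diff(grid))
        bits = sample_meiosis_bits(ped.n_meioses, thetas, rng_ibd)
        for mi, (child, slot) in enumerate(ped.meioses):
            mem = ped.member(child)
            parent = mem.father if slot == 0 else mem.mother
            pat = lab[:, ped.slot_index(parent, 0)]
            mat = lab[:, ped.slot_index(parent, 1)]
            lab[:, ped.slot_index(child, slot)] = np.where(bits[:, mi] == 0, pat, mat)
        for ci, iid in enumerate(ped.individuals):
            truth_labels[:, 2 * col_of[iid]] = lab[:, 2 * ci]
            truth_labels[:, 2 * col_of[iid] + 1] = lab[:, 2 * ci + 1]
        fgl_offset += 2 * ped.n_founders

    # FGL alleles (linkage equilibrium given the labels)
    n_fgl = 2 * n_founders_total + len(bridge_by_group)
    alleles = (rng_geno.random((L, n_fgl)) < grid_fr[:, None]).astype(np.int8)
    for gfgl in hidden_fgl.values():
        alleles[qtl_gi, gfgl] = 1  # the shared segment carries the risk allele

    li = np.arange(L)[:, None]
    true_dosage = (alleles[li, truth_labels[:, 0::2]]
                   + alleles[li, truth_labels[:, 1::2]]).astype(np.int8)  # (L, n)

    # genotype emission with per-allele error
    eps = config.genotype_error
    a0 = alleles[li, truth_labels[:, 0::2]]
    a1 = alleles[li, truth_labels[:, 1::2]]
    if eps > 0:
        flip0 = rng_geno.random(a0.shape) < eps
        flip1 = rng_geno.random(a1.shape) < eps
        g_all = ((a0 ^ flip0) + (a1 ^ flip1)).astype(np.int8)
    else:
        g_all = (a0 + a1).astype(np.int8)

    sparse_panel = PanelData(sparse_names, sparse_pos, sparse_fr, all_inds,
                             g_all[sparse_gi], eps=max(eps, 0.001))
    # dense-typed subset: bridge individuals plus a per-pedigree fraction
    typed = list(bridge_ids)
    if config.dense_typed_fraction > 0:
        for ped in peds:
            pool = [i for i in ped.individuals if i not in typed]
            k = int(round(config.dense_typed_fraction * len(ped)))
            pick = rng_geno.choice(len(pool), size=min(k, len(pool)), replace=False)
            typed.extend(pool[j] for j in sorted(pick))
    typed_cols = [col_of[i] for i in typed]
    dense_panel = PanelData(dense_names, dense_pos, dense_fr, typed,
                            g_all[dense_gi][:, typed_cols], eps=max(eps, 0.001))
    dense_true = PanelData(dense_names, dense_pos, dense_fr, all_inds,
                           true_dosage[dense_gi], eps=0.0)

    # traits from the true QTL genotypes
    qg = true_dosage[qtl_gi]
    mu = np.asarray(config.qtl.mu)
    R = config.n_trait_replicates
    yv = mu[qg][:, None] + rng_trait.normal(
        0.0, np.sqrt(config.qtl.sigma2), (len(all_inds), R))
    traits = pd.DataFrame(yv, index=all_inds,
                          columns=[f"rep{r + 1}" for r in range(R)])

    truth_graph = IBDGraphSet.from_dense(all_inds, sparse_pos,
                                         [truth_labels[sparse_gi]])
    pairs = [(a, b) for ids in bridge_by_group
             for x, a in enumerate(ids) for b in ids[x + 1:]]
    truth = TruthRecord(truth_graph, {iid: int(qg[col_of[iid]]) for iid in all_inds},
                        bridge_ids, bridge_by_group, pairs)
    sparse_map = GeneticMap(sparse_names, sparse_pos)
    dense_map = GeneticMap(dense_names, dense_pos)
    return SimDataset(config, peds, sparse_map, dense_map, sparse_panel,
                      dense_panel, dense_true, traits, config.qtl.model(), truth)
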