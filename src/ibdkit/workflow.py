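"""End-to-end IBD-mapping workflow on a simulated or loaded dataset.

Chains the stages: conditional IV sampling per pedigree on the sparse
panel, joint stitching of the bridge individuals on the dense panel,
allele-aware phase alignment, graph merging, and LOD curves for merged and
unmerged (summed per-pedigree) graphs. Each stage can also be run on its
own through the library or the CLI; this module only provides the common
plumbing so scripts stay short.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cryptic import StitchModel, StitchResult, stitch
from .graphs import IBDGraphSet
from .ivsampler import sample_ivs
from .lod import LODCurve, lod_curve, null_loglik, summed_lod_curve
from .merge import allele_align, merge_graphs
from .simulate import SimDataset

__all__ = ["MappingResult", "sample_pedigree_graphs", "stitch_bridge",
           "run_ibd_mapping"]


@dataclass
class MappingResult:
    ped_graphs: list[IBDGraphSet]
    bridge: StitchResult
    merged: IBDGraphSet
    merged_curve: LODCurve
    unmerged_curve: LODCurve


def sample_pedigree_graphs(ds: SimDataset, K: int, seed: int) -> list[IBDGraphSet]:
    """Conditional IV realizations for every pedigree of a dataset."""
    out = []
    for i, ped in enumerate(ds.pedigrees):
        out.append(sample_ivs(ped, ds.sparse, K=K, seed=seed + 101 * i))
    return out


def stitch_bridge(ds: SimDataset, K: int, seed: int,
                  model: StitchModel | None = None) -> StitchResult:
    """Joint IBD realizations on the bridge individuals from the dense panel."""
    panel = ds.dense.subset_individuals(ds.truth.bridge_individuals)
    return stitch(panel, model or StitchModel(), K=K, seed=seed)


def run_ibd_mapping(ds: SimDataset, K: int, seed: int, n_replicates: int | None = None,
                    null_M: int = 10_000, stitch_model: StitchModel | None = None) -> MappingResult:
    """The merged-versus-unmerged LOD contrast on one dataset.

    ``n_replicates`` restricts to the first trait replicates (default all).
    The null is per pedigree (no cross-pedigree IBD under no linkage); the
    merged curve uses the sum of the per-pedigree nulls.
    """
    traits = ds.traits if n_replicates is None else ds.traits.iloc[:, :n_replicates]
    ped_graphs = sample_pedigree_graphs(ds, K, seed)
    bridge = stitch_bridge(ds, K, seed + 7919, stitch_model)
    align = allele_align(ped_graphs, bridge, ds.sparse)
    groups = ds.truth.groups if ds.truth.groups else None
    merged = merge_graphs(ped_graphs, bridge.graphs, slot_alignment=align,
                          groups=groups)
    nulls = [null_loglik([ped], traits, ds.qtl_model, M=null_M, seed=seed + 31 * i)
             for i, ped in enumerate(ds.pedigrees)]
    merged_curve = lod_curve(merged, traits, ds.qtl_model,
                             np.sum(nulls, axis=0), source="merged")
    unmerged_curve = summed_lod_curve(ped_graphs, traits, ds.qtl_model, nulls)
    return MappingResult(ped_graphs, bridge, merged, merged_curve, unmerged_curve)
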