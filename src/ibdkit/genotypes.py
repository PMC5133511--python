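"""Biallelic genotype panels: containers, error model, and I/O.

Genotypes are alternate-allele counts 0/1/2, with -1 for missing. The
observation model is a symmetric per-allele error: each transmitted allele
is read correctly with probability 1 - eps and flipped with probability
eps, independently; an unordered heterozygote sums its two ordered read
events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PanelData", "obs_given_dosage", "read_genotypes_tabular",
           "write_genotypes_tabular", "read_frequencies", "write_frequencies",
           "read_genotypes_vcf"]

MISSING = -1


def obs_given_dosage(eps: float) -> np.ndarray:
    """Return the 3x4 table ``T[true_dosage, obs]`` of observation probabilities.

    Columns 0..2 are the observed unordered genotypes; column 3 is the
    missing code and is identically 1 (missing observations carry no
    information).
    """
    if not 0.0 <= eps < 0.5:
        raise ValueError("per-allele error rate must lie in [0, 0.5)")
    T = np.empty((3, 4))
    for d in range(3):
        # read-alt probabilities of the two true alleles
        ra = eps if d == 0 else (1 - eps)
        rb = eps if d < 2 else (1 - eps)
        T[d, 0] = (1 - ra) * (1 - rb)
        T[d, 1] = ra * (1 - rb) + (1 - ra) * rb
        T[d, 2] = ra * rb
    T[:, 3] = 1.0
    return T


@dataclass
class PanelData:
    """A biallelic marker panel: map positions, frequencies, genotypes.

    ``genotypes`` has shape ``(L, n)`` (markers x individuals), values in
    {0, 1, 2, -1}. ``freqs`` are alternate-allele frequencies.
    """

    markers: list[str]
    positions_cm: np.ndarray
    freqs: np.ndarray
    individuals: list[str]
    genotypes: np.ndarray
    eps: float = 0.01

    def __post_init__(self):
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        L, n = self.genotypes.shape
        if not (len(self.markers) == self.positions_cm.size == self.freqs.size == L):
            raise ValueError("marker metadata lengths disagree with genotype rows")
        if len(self.individuals) != n:
            raise ValueError("individual list disagrees with genotype columns")
        if np.any((self.freqs <= 0) | (self.freqs >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def column(self, iid: str) -> np.ndarray:
        return self.genotypes[:, self.individuals.index(iid)]

    def subset_individuals(self, ids) -> "PanelData":
        idx = [self.individuals.index(i) for i in ids]
        return PanelData(self.markers, self.positions_cm, self.freqs,
                         list(ids), self.genotypes[:, idx], self.eps)


# ---------------------------------------------------------------------------
# tabular I/O (rows = markers, columns = individuals)
# ---------------------------------------------------------------------------


def write_genotypes_tabular(path, panel: PanelData) -> None:
    df = pd.DataFrame(
        panel.genotypes.astype(object), index=panel.markers, columns=panel.individuals
    )
    df[df == MISSING] = "NA"
    df.index.name = "marker"
    df.to_csv(path, sep="\t")


def read_genotypes_tabular(path, positions_cm=None, freqs=None, eps=0.01) -> PanelData:
    """Read a marker-by-individual 0/1/2/NA matrix.

    ``positions_cm`` and ``freqs`` may be arrays aligned to the file's
    marker order, or mappings from marker id.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    markers = [str(m) for m in df.index]
    G = df.replace("NA", str(MISSING)).to_numpy(dtype=float).astype(np.int8)
    pos = _aligned(positions_cm, markers, "positions_cm")
    if pos is None:
        pos = np.arange(len(markers), dtype=float)
    fr = _aligned(freqs, markers, "freqs")
    if fr is None:
        fr = np.full(len(markers), 0.5)
    return PanelData(markers, pos, fr, [str(c) for c in df.columns], G, eps)


def _aligned(values, markers, what):
    if values is None:
        return None
    if isinstance(values, dict):
        try:
            return np.array([values[m] for m in markers], dtype=float)
        except KeyError as e:
            raise ValueError(f"{what}: no entry for marker {e.args[0]!r}")
    values = np.asarray(values, dtype=float)
    if values.size != len(markers):
        raise ValueError(f"{what}: length {values.size} != {len(markers)} markers")
    return values


def write_frequencies(path, markers, freqs) -> None:
    with open(path, "w") as fh:
        fh.write("# marker freq\n")
        for m, f in zip(markers, freqs):
            fh.write(f"{m} {float(f)!r}\n")


def read_frequencies(path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m, f = line.split()[:2]
            out[m] = float(f)
    return out


def read_genotypes_vcf(path, positions_cm=None, eps=0.01) -> PanelData:
    """Read biallelic sites from a VCF into a :class:`PanelData`.

    Allele frequencies are taken from the ``AF`` INFO field when present,
    otherwise computed from the sample genotypes. Requires :mod:`cyvcf2`.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    markers, rows, freqs, bps = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gt = np.asarray(var.gt_types)
        # cyvcf2: 0=hom-ref 1=het 2=unknown 3=hom-alt
        row = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        bps.append(var.POS)
        rows.append(row.astype(np.int8))
        af = var.INFO.get("AF")
        if af is None:
            obs = row[row >= 0]
            af = obs.sum() / (2.0 * max(len(obs), 1))
        freqs.append(float(af if not isinstance(af, tuple) else af[0]))
    G = np.array(rows, dtype=np.int8)
    pos = _aligned(positions_cm, markers, "positions_cm")
    if pos is None:
        pos = np.asarray(bps, dtype=float) / 1e6  # 1 cM/Mb fallback
    fr = np.clip(np.asarray(freqs), 1e-6, 1 - 1e-6)
    return PanelData(markers, pos, fr, individuals, G, eps)
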