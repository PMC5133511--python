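import numpy as np
import pytest

from ibdkit.pedigree import Member, Pedigree


@pytest.fixture
def trio():
    return Pedigree("t", [
        Member("pa", None, None, 1),
        Member("ma", None, None, 2),
        Member("ch", "pa", "ma", 1),
    ])


@pytest.fixture
def sibpair():
    return Pedigree("s", [
        Member("pa", None, None, 1),
        Member("ma", None, None, 2),
        Member("s1", "pa", "ma", 1),
        Member("s2", "pa", "ma", 2),
    ])


@pytest.fixture
def three_gen():
    """Six members over three generations (8 meioses)."""
    return Pedigree("g", [
        Member("gf", None, None, 1),
        Member("gm", None, None, 2),
        Member("fa", "gf", "gm", 1),
        Member("mo", None, None, 2),
        Member("c1", "fa", "mo", 1),
        Member("c2", "fa", "mo", 2),
    ])


@pytest.fixture(scope="session")
def mini_dataset():
    from ibdkit.simulate import mini_config, simulate

    return simulate(mini_config(seed=20260925))


def brute_force_partition_likelihood(labels, genotypes, p, eps=0.0):
    """Independent enumeration oracle for the single-locus partition
    genotype likelihood (sum over class-allele assignments)."""
    import itertools

    labels = np.asarray(labels)
    genotypes = np.asarray(genotypes)
    n = genotypes.size
    obs = [i for i in range(n) if genotypes[i] >= 0]
    classes = sorted({int(labels[2 * i + s]) for i in obs for s in (0, 1)})
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(classes)):
        amap = dict(zip(classes, assign))
        w = 1.0
        for a in assign:
            w *= p if a else (1 - p)
        for i in obs:
            a1 = amap[int(labels[2 * i])]
            a2 = amap[int(labels[2 * i + 1])]
            r1 = (1 - eps) if a1 else eps
            r2 = (1 - eps) if a2 else eps
            g = int(genotypes[i])
            if g == 0:
                w *= (1 - r1) * (1 - r2)
            elif g == 2:
                w *= r1 * r2
            else:
                w *= r1 * (1 - r2) + (1 - r1) * r2
        total += w
    return total


def brute_force_trait_likelihood(labels, traits, model):
    """Independent enumeration oracle for the trait likelihood of a
    partition under the biallelic QTL model."""
    import itertools
    from math import exp, pi, sqrt

    labels = np.asarray(labels)
    traits = np.asarray(traits, dtype=float)
    classes = sorted(set(labels.tolist()))
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(classes)):
        amap = dict(zip(classes, assign))
        w = 1.0
        for a in assign:
            w *= model.q if a else (1 - model.q)
        for i, y in enumerate(traits):
            if np.isnan(y):
                continue
            d = amap[int(labels[2 * i])] + amap[int(labels[2 * i + 1])]
            w *= exp(-0.5 * (y - model.mu[d]) ** 2 / model.sigma2) / sqrt(
                2 * pi * model.sigma2)
        total += w
    return total
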