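import numpy as np
import pandas as pd
import pytest

from famburden.genotype import GenotypeMatrix, minor_allele_freq
from famburden.pedigree import Pedigree, PedigreeRecord


def make_pedigree(rows):
    """rows: (family, individual, father, mother, sex) with None for missing."""
    return Pedigree([PedigreeRecord(*r) for r in rows])


def make_genotypes(dosages, genes=None, subjects=None, compute_maf=True):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    meta = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "gene": genes if genes is not None else [None] * m,
    })
    g = GenotypeMatrix(
        dosages, meta,
        subjects if subjects is not None else [f"s{i}" for i in range(n)],
    )
    if compute_maf:
        minor_allele_freq(g)
    return g


def pedigree_library():
    """Hand-constructed small pedigrees (named), including inbred loops."""
    lib = {}
    lib["trio"] = [
        ("F1", "dad", None, None, 1), ("F1", "mom", None, None, 2),
        ("F1", "kid", "dad", "mom", 1),
    ]
    lib["nuclear"] = [
        ("F1", "p1", None, None, 1), ("F1", "p2", None, None, 2),
        ("F1", "c1", "p1", "p2", 1), ("F1", "c2", "p1", "p2", 2),
        ("F1", "c3", "p1", "p2", 1),
    ]
    lib["three_gen"] = [
        ("F1", "gf", None, None, 1), ("F1", "gm", None, None, 2),
        ("F1", "dad", "gf", "gm", 1), ("F1", "mom", None, None, 2),
        ("F1", "kid", "dad", "mom", 2),
    ]
    lib["fullsib_mating"] = [
        ("F1", "p1", None, None, 1), ("F1", "p2", None, None, 2),
        ("F1", "s1", "p1", "p2", 1), ("F1", "s2", "p1", "p2", 2),
        ("F1", "inbred", "s1", "s2", 1),
    ]
    lib["halfsib_mating"] = [
        ("F1", "dad", None, None, 1), ("F1", "m1", None, None, 2),
        ("F1", "m2", None, None, 2),
        ("F1", "h1", "dad", "m1", 1), ("F1", "h2", "dad", "m2", 2),
        ("F1", "inbred", "h1", "h2", 2),
    ]
    lib["cousin_mating"] = [
        ("F1", "gf", None, None, 1), ("F1", "gm", None, None, 2),
        ("F1", "a", "gf", "gm", 1), ("F1", "b", "gf", "gm", 2),
        ("F1", "aw", None, None, 2), ("F1", "bh", None, None, 1),
        ("F1", "c1", "a", "aw", 1), ("F1", "c2", "bh", "b", 2),
        ("F1", "inbred", "c1", "c2", 1),
    ]
    lib["half_sibs"] = [
        ("F1", "dad", None, None, 1), ("F1", "m1", None, None, 2),
        ("F1", "m2", None, None, 2),
        ("F1", "h1", "dad", "m1", 1), ("F1", "h2", "dad", "m2", 2),
    ]
    lib["two_families"] = [
        ("F1", "a1", None, None, 1), ("F1", "a2", None, None, 2),
        ("F1", "a3", "a1", "a2", 1),
        ("F2", "b1", None, None, 1), ("F2", "b2", None, None, 2),
        ("F2", "b3", "b1", "b2", 2),
    ]
    lib["chain"] = [
        ("F1", "g1", None, None, 1), ("F1", "g1w", None, None, 2),
        ("F1", "g2", "g1", "g1w", 1), ("F1", "g2w", None, None, 2),
        ("F1", "g3", "g2", "g2w", 1), ("F1", "g3w", None, None, 2),
        ("F1", "g4", "g3", "g3w", 1), ("F1", "g4w", None, None, 2),
        ("F1", "g5", "g4", "g4w", 2),
    ]
    lib["double_cousins"] = [
        ("F1", "pa", None, None, 1), ("F1", "pb", None, None, 2),
        ("F1", "qa", None, None, 1), ("F1", "qb", None, None, 2),
        ("F1", "s1", "pa", "pb", 1), ("F1", "s2", "pa", "pb", 2),
        ("F1", "t1", "qa", "qb", 1), ("F1", "t2", "qa", "qb", 2),
        ("F1", "u", "s1", "t2", 1), ("F1", "v", "t1", "s2", 2),
    ]
    lib["avuncular"] = [
        ("F1", "gf", None, None, 1), ("F1", "gm", None, None, 2),
        ("F1", "son", "gf", "gm", 1), ("F1", "dau", "gf", "gm", 2),
        ("F1", "dh", None, None, 1), ("F1", "niece", "dh", "dau", 2),
    ]
    lib["founders_only"] = [
        ("F1", "x1", None, None, 1), ("F1", "x2", None, None, 2),
        ("F1", "x3", None, None, 0),
    ]
    return {name: make_pedigree(rows) for name, rows in lib.items()}


@pytest.fixture
def trio():
    return make_pedigree([
        ("F1", "dad", None, None, 1),
        ("F1", "mom", None, None, 2),
        ("F1", "kid", "dad", "mom", 1),
    ])


@pytest.fixture(scope="session")
def small_study():
    """A small but non-trivial simulated study shared across tests."""
    from famburden.sim import SimConfig, simulate_study

    cfg = SimConfig(
        n_families=3, offspring_range=(3, 4), n_genes=12,
        n_common_markers=400, n_replicates=4, seed=123,
        causal_genes={"gene0001": 0.8},
    )
    return simulate_study(cfg)
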