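import numpy as np
import pandas as pd
import pytest

import sysgenet as sg


@pytest.fixture(scope="session")
def small_map():
    """3 chromosomes x 40 markers, 2.5 Mb spacing (~100 cM per chromosome)."""
    return sg.GeneticMap.regular(n_chrom=3, snps_per_chrom=40, spacing_bp=2_500_000)


@pytest.fixture(scope="session")
def f2_cross(small_map):
    """A 250-animal F2 cross reused by many tests (deterministic seed)."""
    geno, pedigree = sg.simulate_f2_cross(small_map, sg.PedigreeSpec(n_f2=250), seed=11)
    return geno, pedigree


@pytest.fixture(scope="session")
def f2_kinship(f2_cross):
    geno, _ = f2_cross
    return sg.compute_kinship(geno)


def make_genotypes(dosages, positions=None, chroms=None, snps=None, samples=None):
    """Small hand-built GenotypeMatrix for unit tests."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    snps = snps or [f"s{j + 1}" for j in range(m)]
    samples = samples or [f"ind{i + 1}" for i in range(n)]
    positions = positions if positions is not None else [(j + 1) * 1000 for j in range(m)]
    chroms = chroms if chroms is not None else ["1"] * m
    snpmap = pd.DataFrame({"chrom": chroms, "pos": positions})
    return sg.GenotypeMatrix(samples=samples, snps=snps, dosages=d, snpmap=snpmap)
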