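import numpy as np
import pandas as pd
import pytest

from methgene.datatypes import GenotypeMatrix, MethylationMatrix, PairMap, SimScenario
from methgene.synthetic import build_pedigree, kinship_from_pedigree, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_pairs():
    """Five independent SNP-CpG pairs on one chromosome, n=80, one gene."""
    gen = np.random.default_rng(11)
    n, m = 80, 5
    geno = GenotypeMatrix(
        values=gen.integers(0, 3, size=(n, m)).astype(np.int8),
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        positions=np.arange(1, m + 1) * 1000,
        chromosomes=np.full(m, "1"),
    )
    meth = MethylationMatrix(
        values=gen.random((n, m)),
        cpg_ids=np.array([f"c{j}" for j in range(m)]),
        positions=np.arange(1, m + 1) * 1000 + 100,
        chromosomes=np.full(m, "1"),
    )
    pairs = PairMap(
        snp_ids=geno.snp_ids,
        cpg_ids=meth.cpg_ids,
        snp_index=np.arange(m),
        cpg_index=np.arange(m),
        gene_assignments={"G1": np.arange(m)},
        gene_categories={"G1": "noncausal"},
    )
    r = gen.standard_normal(n)
    return r, geno, meth, pairs


@pytest.fixture(scope="session")
def null_cohort():
    """A small cohort with no causal effects."""
    m = 8
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "maf": np.linspace(0.1, 0.45, m),
            "h2": 0.0,
            "cpg_id": [f"c{j}" for j in range(m)],
        }
    )
    cpgs = pd.DataFrame(
        {"cpg_id": [f"c{j}" for j in range(m)], "chrom": "1", "pos": np.arange(1, m + 1) * 1000 + 137}
    )
    scenario = SimScenario(n_individuals=120, snps=snps, cpgs=cpgs)
    return simulate_cohort(scenario, seed=5)


@pytest.fixture(scope="session")
def small_pedigree():
    return build_pedigree(40, sibship_sizes=(2, 3), seed=3)


@pytest.fixture(scope="session")
def small_kinship(small_pedigree):
    return kinship_from_pedigree(small_pedigree)
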