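"""Shared fixtures: small simulated datasets and hand-built genotype tables."""

import numpy as np
import pytest

from crushmdr.data import GenotypeDataset
from crushmdr.simulate import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def sigma0_sim():
    """One planted gene, zero trait noise, 10 SNPs: a noiseless fixture where
    the planted pair is unambiguously the strongest signal."""
    spec = SimulationSpec(
        n_genes=1, maf=0.4, heritability=0.2, trait_sd=0.0,
        n_samples=400, n_total_snps=10, seed=11,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def strong_sim():
    """Two planted genes at strong effect size among 100 SNPs (n=2000)."""
    spec = SimulationSpec(
        n_genes=2, maf=0.4, heritability=0.2, trait_sd=0.05,
        n_samples=2000, n_total_snps=100, seed=7,
    )
    return simulate_dataset(spec)


@pytest.fixture
def small_random_dataset():
    """Unstructured genotypes with an independent trait (null dataset)."""
    rng = np.random.default_rng(42)
    geno = rng.integers(0, 3, size=(60, 8))
    pheno = rng.normal(size=60)
    return GenotypeDataset(
        genotypes=geno,
        phenotype=pheno,
        snp_ids=[f"s{i}" for i in range(8)],
        phenotype_kind="quantitative",
    )


def make_dataset(genotypes, phenotype, kind="quantitative"):
    genotypes = np.asarray(genotypes)
    return GenotypeDataset(
        genotypes=genotypes,
        phenotype=np.asarray(phenotype, dtype=float),
        snp_ids=[f"s{i}" for i in range(genotypes.shape[1])],
        phenotype_kind=kind,
    )
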