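"""Hierarchical quantitative-trait epistasis simulator.

Each simulated *gene* is a pure-epistasis two-SNP penetrance model: a 3x3
table f(g1, g2) whose row and column marginals under Hardy-Weinberg
genotype frequencies are all equal, so neither SNP has a main effect, yet
the table carries genetic variance with a prescribed broad-sense
heritability

    h^2 = sum_ij p_ij (f_ij - K)^2 / (K (1 - K)),   K = sum_ij p_ij f_ij.

A gene's continuous product for a sample is drawn Normal(f(g1, g2), sigma);
the phenotype is the sum of the gene products (additivity *between* genes,
pure non-additivity *within* genes).  Functional SNP pairs are padded with
independent noise SNPs (MAF uniform in [0.05, 0.5]) and all columns are
shuffled so detection cannot exploit ordering.

Tables are generated by projecting a random deviation table onto the
zero-marginal-effect subspace (iterated HWE-weighted row/column centering)
and scaling the deviations around a baseline K0 = 0.5 to hit the target
heritability exactly; draws that would clip outside [0, 1] are rejected and
retried.  This construction is deterministic given the RNG stream and
exactly verifiable, unlike a stochastic table search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeDataset, TruthSet

__all__ = [
    "PenetranceModel",
    "SimulationSpec",
    "SimulationResult",
    "hwe_genotype_frequencies",
    "table_heritability",
    "marginal_penetrances",
    "generate_penetrance_table",
    "simulate_dataset",
]

_MARGINAL_TOL = 1e-9
_H2_REL_TOL = 1e-6
_BASELINE_K = 0.5


@dataclass
class PenetranceModel:
    """One simulated gene: a 3x3 pure-epistasis penetrance table."""

    table: np.ndarray  # f[g1, g2], values in [0, 1]
    maf: float
    heritability: float  # realized h^2 of the table
    mean_k: float  # population mean of f under HWE


@dataclass
class SimulationSpec:
    """One cell of the simulation grid.

    The defaults are one grid point; the study grid varies n_genes in
    {2, 4}, maf in {0.2, 0.4}, heritability in {0.001, 0.01, 0.1, 0.2},
    trait_sd in {0.05, 0.1, 0.2, 0.3}, n_samples in {2000, 8000} and
    n_total_snps in {100, 1000}.
    """

    n_genes: int = 2
    maf: float = 0.4
    heritability: float = 0.2
    trait_sd: float = 0.05
    n_samples: int = 2000
    n_total_snps: int = 100
    replicates: int = 10
    seed: int = 0
    noise_after_sum: bool = False  # one Normal(0, sigma) after summing genes

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must be in (0, 1)")
        if self.trait_sd < 0:
            raise ValueError("trait_sd must be >= 0")
        if self.n_total_snps < 2 * self.n_genes:
            raise ValueError("n_total_snps must cover 2 SNPs per gene")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class SimulationResult:
    """A simulated dataset with its ground truth and gene models."""

    dataset: GenotypeDataset
    truth: TruthSet
    gene_models: list = field(default_factory=list)
    functional_indices: list = field(default_factory=list)

    def __iter__(self):
        # allows `dataset, truth = simulate_dataset(...)`
        return iter((self.dataset, self.truth))


def hwe_genotype_frequencies(maf: float) -> np.ndarray:
    """(q^2, 2pq, p^2) for genotype codes (0, 1, 2) = major-allele count."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf {maf} must be in (0, 0.5]")
    p = 1.0 - maf
    q = maf
    return np.array([q * q, 2 * p * q, p * p])


def _cell_probs(maf: float) -> np.ndarray:
    w = hwe_genotype_frequencies(maf)
    return np.outer(w, w)


def table_heritability(table: np.ndarray, maf: float) -> float:
    """GAMETES broad-sense heritability of a penetrance table."""
    table = np.asarray(table, dtype=float)
    probs = _cell_probs(maf)
    k = float((probs * table).sum())
    if k <= 0.0 or k >= 1.0:
        raise ValueError(f"mean penetrance K={k} leaves h^2 undefined")
    var = float((probs * (table - k) ** 2).sum())
    return var / (k * (1.0 - k))


def marginal_penetrances(table: np.ndarray, maf: float):
    """HWE-weighted row and column marginal penetrances."""
    table = np.asarray(table, dtype=float)
    w = hwe_genotype_frequencies(maf)
    rows = table @ w
    cols = table.T @ w
    return rows, cols


def _project_zero_marginals(dev: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Iterated weighted row/column centering onto the no-main-effect subspace."""
    dev = dev.copy()
    for _ in range(200):
        dev -= np.outer(dev @ w, np.ones(3))
        dev -= np.outer(np.ones(3), dev.T @ w)
        if max(np.abs(dev @ w).max(), np.abs(dev.T @ w).max()) < 1e-15:
            break
    return dev


def generate_penetrance_table(
    maf: float,
    target_h2: float,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> PenetranceModel:
    """Draw a pure-epistasis table with exactly the target heritability."""
    if not 0.0 < target_h2 < 1.0:
        raise ValueError("target_h2 must be in (0, 1)")
    w = hwe_genotype_frequencies(maf)
    probs = _cell_probs(maf)
    for _ in range(max_tries):
        dev = rng.normal(size=(3, 3))
        dev = _project_zero_marginals(dev, w)
        var = float((probs * dev**2).sum())
        if var < 1e-12:
            continue
        k0 = _BASELINE_K
        scale = np.sqrt(target_h2 * k0 * (1.0 - k0) / var)
        table = k0 + scale * dev
        if table.min() < 0.0 or table.max() > 1.0:
            continue  # would need clipping: reject and retry
        h2 = table_heritability(table, maf)
        if abs(h2 - target_h2) > _H2_REL_TOL * target_h2:
            continue
        rows, cols = marginal_penetrances(table, maf)
        k = float((probs * table).sum())
        if (
            np.abs(rows - k).max() > _MARGINAL_TOL
            or np.abs(cols - k).max() > _MARGINAL_TOL
        ):
            continue
        return PenetranceModel(
            table=table, maf=maf, heritability=h2, mean_k=k
        )
    raise RuntimeError(
        f"could not generate a feasible table for maf={maf}, h2={target_h2} "
        f"in {max_tries} tries"
    )


def _sample_genotypes(
    n: int, maf: float, rng: np.random.Generator
) -> np.ndarray:
    return rng.choice(3, size=n, p=hwe_genotype_frequencies(maf))


def simulate_dataset(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> SimulationResult:
    """Simulate one dataset under a grid-cell specification.

    Returns a :class:`SimulationResult`; iterating it yields
    ``(dataset, truth)``.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    genes = [
        generate_penetrance_table(spec.maf, spec.heritability, rng)
        for _ in range(spec.n_genes)
    ]
    n = spec.n_samples
    n_functional = 2 * spec.n_genes
    n_noise = spec.n_total_snps - n_functional

    functional = np.empty((n, n_functional), dtype=np.int8)
    phenotype = np.zeros(n)
    for g, model in enumerate(genes):
        g1 = _sample_genotypes(n, spec.maf, rng)
        g2 = _sample_genotypes(n, spec.maf, rng)
        functional[:, 2 * g] = g1
        functional[:, 2 * g + 1] = g2
        means = model.table[g1, g2]
        if spec.trait_sd > 0 and not spec.noise_after_sum:
            phenotype += rng.normal(means, spec.trait_sd)
        else:
            phenotype += means
    if spec.trait_sd > 0 and spec.noise_after_sum:
        phenotype += rng.normal(0.0, spec.trait_sd, size=n)

    noise = np.empty((n, n_noise), dtype=np.int8)
    noise_mafs = rng.uniform(0.05, 0.5, size=n_noise)
    for j in range(n_noise):
        noise[:, j] = _sample_genotypes(n, noise_mafs[j], rng)

    full = np.concatenate([functional, noise], axis=1)
    positions = rng.permutation(spec.n_total_snps)
    shuffled = np.empty_like(full)
    shuffled[:, positions] = full  # original column j lands at positions[j]
    width = len(str(spec.n_total_snps))
    snp_ids = [f"snp{i:0{width}d}" for i in range(spec.n_total_snps)]

    functional_ids = [snp_ids[positions[j]] for j in range(n_functional)]
    gene_pairs = [
        (functional_ids[2 * g], functional_ids[2 * g + 1])
        for g in range(spec.n_genes)
    ]
    dataset = GenotypeDataset(
        genotypes=shuffled,
        phenotype=phenotype,
        snp_ids=snp_ids,
        phenotype_kind="quantitative",
    )
    truth = TruthSet(
        functional_snp_ids=[s for pair in gene_pairs for s in pair],
        genes=gene_pairs,
    )
    return SimulationResult(
        dataset=dataset,
        truth=truth,
        gene_models=genes,
        functional_indices=[int(positions[j]) for j in range(n_functional)],
    )
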