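"""Entropy-based pairwise interaction information ("expert knowledge").

For SNPs A, B and a binary class C the interaction gain is

    IG(A;B;C) = I(A,B;C) - I(A;C) - I(B;C)

where (A,B) is the 9-category joint genotype variable.  Positive gain means
the pair carries synergistic information about the class beyond its main
effects; negative gain indicates redundancy (e.g. linkage disequilibrium).
All quantities use the plug-in (maximum-likelihood) estimator in bits, with
no bias correction, matching the standard MDR entropy tooling.

A continuous trait is first binarized at its overall mean — the same
high/low semantics QMDR applies per genotype cell — so that the discrete
information measures apply (median split available by flag).

The full pairwise gain matrix is the lookup table used for sensible
initialization of the evolutionary search; each SNP's argmax row entry is
its *best partner*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GenotypeDataset

__all__ = [
    "ExpertKnowledgeTable",
    "shannon_entropy",
    "mutual_information",
    "interaction_gain",
    "binarize_trait",
    "build_expert_knowledge",
]


@dataclass
class ExpertKnowledgeTable:
    """Pairwise interaction-gain lookup table.

    gain : symmetric (n_snps, n_snps) matrix of interaction gains in bits,
        zero diagonal.
    best_partner : per-SNP argmax of the gain row (never the SNP itself).
    class_vector : the binary class C the gains were computed against.
    """

    gain: np.ndarray
    best_partner: np.ndarray
    class_vector: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.best_partner = np.asarray(self.best_partner, dtype=np.int64)
        n = self.gain.shape[0]
        if self.gain.shape != (n, n):
            raise ValueError("gain must be square")
        if not np.allclose(self.gain, self.gain.T):
            raise ValueError("gain matrix must be symmetric")
        if not np.allclose(np.diag(self.gain), 0.0):
            raise ValueError("gain diagonal must be zero")
        if np.any(self.best_partner == np.arange(n)):
            raise ValueError("best_partner[i] must differ from i")

    @property
    def n_snps(self) -> int:
        return self.gain.shape[0]

    def top_partners(self, snp: int, k: int = 1) -> np.ndarray:
        """Indices of the k highest-gain partners of ``snp``."""
        row = self.gain[snp].copy()
        row[snp] = -np.inf
        return np.argsort(row)[::-1][:k]


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def shannon_entropy(counts) -> float:
    """Shannon entropy in bits of a categorical distribution given as counts."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("all-zero counts: entropy undefined")
    return _entropy_from_counts(counts.astype(float))


def _encode(x: np.ndarray) -> tuple[np.ndarray, int]:
    _, inv = np.unique(x, return_inverse=True)
    return inv.astype(np.int64), int(inv.max()) + 1


def mutual_information(x, c) -> float:
    """Plug-in mutual information I(X;C) in bits; always >= 0."""
    x = np.asarray(x)
    c = np.asarray(c)
    if x.shape != c.shape:
        raise ValueError("length mismatch between X and C")
    xi, nx = _encode(x)
    ci, nc = _encode(c)
    hx = _entropy_from_counts(np.bincount(xi, minlength=nx).astype(float))
    hc = _entropy_from_counts(np.bincount(ci, minlength=nc).astype(float))
    hxc = _entropy_from_counts(
        np.bincount(xi * nc + ci, minlength=nx * nc).astype(float)
    )
    return hx + hc - hxc


def interaction_gain(a, b, c) -> float:
    """IG(A;B;C) = I(A,B;C) - I(A;C) - I(B;C) in bits."""
    a = np.asarray(a)
    b = np.asarray(b)
    c = np.asarray(c)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("A, B and C must have equal length")
    ai, na = _encode(a)
    bi, nb = _encode(b)
    ab = ai * nb + bi
    return (
        mutual_information(ab, c)
        - mutual_information(a, c)
        - mutual_information(b, c)
    )


def binarize_trait(phenotype, split: str = "mean") -> np.ndarray:
    """Binary class from a continuous trait: 1 iff value > threshold.

    The default threshold is the overall mean, mirroring QMDR's high/low
    construction; ``split="median"`` is available.
    """
    y = np.asarray(phenotype, dtype=float)
    if np.all(y == y[0]):
        raise ValueError("constant phenotype carries no information")
    if split == "mean":
        thr = y.mean()
    elif split == "median":
        thr = np.median(y)
    else:
        raise ValueError(f"unknown split {split!r}")
    return (y > thr).astype(np.int64)


def build_expert_knowledge(
    dataset: GenotypeDataset, split: str = "mean"
) -> ExpertKnowledgeTable:
    """Compute all n(n-1)/2 pairwise interaction gains for a dataset.

    The class is the binary endpoint directly, or the trait binarized at the
    mean for a quantitative phenotype.  Deterministic.
    """
    if dataset.n_snps < 2:
        raise ValueError("need at least two SNPs")
    if dataset.phenotype_kind == "binary":
        c = dataset.phenotype.astype(np.int64)
    else:
        c = binarize_trait(dataset.phenotype, split=split)
    X = dataset.genotypes.astype(np.int64)
    n, m = X.shape
    hc = _entropy_from_counts(np.bincount(c, minlength=2).astype(float))

    # per-SNP I(A;C), then the pairwise joint terms
    mi_single = np.empty(m)
    h_single = np.empty(m)
    for i in range(m):
        counts = np.bincount(X[:, i], minlength=3).astype(float)
        h_single[i] = _entropy_from_counts(counts)
        joint = np.bincount(X[:, i] * 2 + c, minlength=6).astype(float)
        mi_single[i] = h_single[i] + hc - _entropy_from_counts(joint)

    gain = np.zeros((m, m))
    for i in range(m - 1):
        ai = X[:, i]
        for j in range(i + 1, m):
            ab = ai * 3 + X[:, j]
            hab = _entropy_from_counts(np.bincount(ab, minlength=9).astype(float))
            habc = _entropy_from_counts(
                np.bincount(ab * 2 + c, minlength=18).astype(float)
            )
            i_ab_c = hab + hc - habc
            g = i_ab_c - mi_single[i] - mi_single[j]
            gain[i, j] = gain[j, i] = g

    masked = gain.copy()
    np.fill_diagonal(masked, -np.inf)
    best_partner = masked.argmax(axis=1)
    return ExpertKnowledgeTable(gain=gain, best_partner=best_partner, class_vector=c)
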