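"""The MDR/QMDR constructive-induction kernel.

Multifactor dimensionality reduction (MDR) collapses the multilocus
genotype table spanned by K SNPs into a single binary attribute.  For a
quantitative trait (QMDR) a genotype cell is labeled *high-level* when its
mean trait strictly exceeds the overall mean, otherwise *low-level*; the
pooled high/low groups are then compared with a two-sample t-test whose
statistic serves as the association score.  For a binary endpoint the
classic rule applies: a cell is high-risk when its case/control ratio
strictly exceeds a threshold T.

Equality with the grand mean (or ratio equal to T) labels a cell low:
"exceeds" is read strictly.  Unobserved cells are recorded as ``empty`` and
contribute nothing; if ever queried they behave as low.  Degenerate group
layouts (an empty group, or zero pooled variance) score t = 0 with
``valid=False`` instead of raising, so a stochastic search over models can
keep running.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .data import GenotypeDataset

__all__ = [
    "ConstructedAttribute",
    "ModelScore",
    "construct_attribute_quantitative",
    "construct_attribute_binary",
    "t_statistic",
    "score_model",
    "kfold_qmdr_score",
    "DEFAULT_MAX_K",
]

DEFAULT_MAX_K = 10  # 3^K cells empty out long before this; guards blow-up

HIGH = "high"
LOW = "low"
EMPTY = "empty"


@dataclass
class ConstructedAttribute:
    """Binary attribute produced by pooling multilocus genotype cells."""

    labels: np.ndarray  # 1 = high-level group G1, 0 = low-level group G0
    cell_map: dict  # genotype tuple -> "high" | "low" | "empty"
    cell_means: dict  # genotype tuple -> mean trait (observed cells only)
    grand_mean: float


@dataclass
class ModelScore:
    """The three search objectives for one candidate SNP set."""

    t_statistic: float
    mean_interaction_info: float
    size: int
    valid: bool = True


def _check_indices(snp_indices, n_snps: int, max_k: int) -> tuple[int, ...]:
    snps = tuple(int(i) for i in snp_indices)
    if len(snps) == 0:
        raise ValueError("model must contain at least one SNP")
    if len(set(snps)) != len(snps):
        raise ValueError(f"duplicate SNP indices in {snps}")
    if len(snps) > max_k:
        raise ValueError(f"model order {len(snps)} exceeds maximum {max_k}")
    if any(i < 0 or i >= n_snps for i in snps):
        raise IndexError(f"SNP index out of range in {snps}")
    return snps


def _cell_codes(genotypes: np.ndarray, snps: tuple[int, ...]) -> np.ndarray:
    """Map each sample to its multilocus cell index in base 3."""
    k = len(snps)
    if k == 1:
        return genotypes[:, snps[0]].astype(np.int64)
    powers = 3 ** np.arange(k, dtype=np.int64)
    return genotypes[:, list(snps)].astype(np.int64) @ powers


def construct_attribute_quantitative(
    dataset: GenotypeDataset,
    snp_indices,
    max_k: int = DEFAULT_MAX_K,
) -> ConstructedAttribute:
    """QMDR constructive induction for a continuous trait.

    A cell is high-level iff its mean trait strictly exceeds the grand mean.
    """
    if dataset.phenotype_kind != "quantitative":
        raise ValueError("construct_attribute_quantitative needs a quantitative trait")
    snps = _check_indices(snp_indices, dataset.n_snps, max_k)
    k = len(snps)
    y = dataset.phenotype
    codes = _cell_codes(dataset.genotypes, snps)
    n_cells = 3**k
    counts = np.bincount(codes, minlength=n_cells)
    sums = np.bincount(codes, weights=y, minlength=n_cells)
    grand_mean = float(y.mean())
    observed = counts > 0
    means = np.full(n_cells, np.nan)
    means[observed] = sums[observed] / counts[observed]
    high = observed & (means > grand_mean)

    cell_map = {}
    cell_means = {}
    for combo in itertools.product((0, 1, 2), repeat=k):
        code = sum(g * 3**i for i, g in enumerate(combo))
        if not observed[code]:
            cell_map[combo] = EMPTY
        else:
            cell_map[combo] = HIGH if high[code] else LOW
            cell_means[combo] = float(means[code])
    labels = high[codes].astype(np.uint8)
    return ConstructedAttribute(labels, cell_map, cell_means, grand_mean)


def construct_attribute_binary(
    dataset: GenotypeDataset,
    snp_indices,
    threshold_T: float | None = None,
    max_k: int = DEFAULT_MAX_K,
) -> ConstructedAttribute:
    """Classic MDR induction for a case/control endpoint.

    A cell is high-risk iff cases/controls strictly exceeds ``threshold_T``
    (default: the overall case/control ratio).  A cell with cases but no
    controls has infinite ratio and is high-risk.
    """
    if dataset.phenotype_kind != "binary":
        raise ValueError("construct_attribute_binary needs a binary endpoint")
    snps = _check_indices(snp_indices, dataset.n_snps, max_k)
    k = len(snps)
    y = dataset.phenotype
    n_cases = float(y.sum())
    n_controls = float(len(y) - n_cases)
    if threshold_T is None:
        if n_controls == 0:
            raise ValueError("no controls: cannot derive default threshold")
        threshold_T = n_cases / n_controls
    if threshold_T <= 0:
        raise ValueError("threshold_T must be positive")
    codes = _cell_codes(dataset.genotypes, snps)
    n_cells = 3**k
    counts = np.bincount(codes, minlength=n_cells)
    cases = np.bincount(codes, weights=y, minlength=n_cells)
    controls = counts - cases
    observed = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(controls > 0, cases / np.maximum(controls, 1), np.inf)
    high = observed & np.where(
        controls > 0, ratio > threshold_T, cases >= 1
    )

    cell_map = {}
    cell_means = {}
    for combo in itertools.product((0, 1, 2), repeat=k):
        code = sum(g * 3**i for i, g in enumerate(combo))
        if not observed[code]:
            cell_map[combo] = EMPTY
        else:
            cell_map[combo] = HIGH if high[code] else LOW
            cell_means[combo] = float(cases[code] / counts[code])
    labels = high[codes].astype(np.uint8)
    return ConstructedAttribute(labels, cell_map, cell_means, float(y.mean()))


def _pooled_t_from_moments(
    n1: float, s1: float, ss1: float, n0: float, s0: float, ss0: float,
    welch: bool = False,
) -> tuple[float, bool]:
    """Two-sample t of (mean G1 - mean G0) from group sums and sums of squares."""
    if n1 < 2 or n0 < 2:
        return 0.0, False
    m1 = s1 / n1
    m0 = s0 / n0
    v1 = max((ss1 - n1 * m1 * m1) / (n1 - 1), 0.0)
    v0 = max((ss0 - n0 * m0 * m0) / (n0 - 1), 0.0)
    if welch:
        se2 = v1 / n1 + v0 / n0
    else:
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n0)
    if se2 <= 0.0:
        return 0.0, False
    return (m1 - m0) / math.sqrt(se2), True


def t_statistic(
    attribute: ConstructedAttribute,
    phenotype: np.ndarray,
    welch: bool = False,
) -> float:
    """Two-sample t comparing the pooled high and low groups.

    Pooled-variance Student's t by default (Welch behind ``welch=True``).
    Returns 0 when either group has fewer than two members or the pooled
    variance vanishes.
    """
    y = np.asarray(phenotype, dtype=float)
    mask = attribute.labels.astype(bool)
    y1 = y[mask]
    y0 = y[~mask]
    t, _valid = _pooled_t_from_moments(
        len(y1), y1.sum(), (y1 * y1).sum(),
        len(y0), y0.sum(), (y0 * y0).sum(),
        welch=welch,
    )
    return t


try:  # single-pass group moments; numpy bincount path used when absent
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None


def _group_moments_py(X, snp_idx, y, y2, grand_mean):
    n = X.shape[0]
    k = snp_idx.shape[0]
    n_cells = 3**k
    counts = np.zeros(n_cells, dtype=np.int64)
    sums = np.zeros(n_cells, dtype=np.float64)
    ssqs = np.zeros(n_cells, dtype=np.float64)
    for i in range(n):
        c = 0
        for j in range(k):
            c = c * 3 + X[i, snp_idx[j]]
        counts[c] += 1
        sums[c] += y[i]
        ssqs[c] += y2[i]
    n1 = 0
    s1 = 0.0
    ss1 = 0.0
    for c in range(n_cells):
        if counts[c] > 0 and sums[c] > grand_mean * counts[c]:
            n1 += counts[c]
            s1 += sums[c]
            ss1 += ssqs[c]
    return n1, s1, ss1


def _group_moments_scratch_py(
    X, snp_idx, y, y2, grand_mean, counts, sums, ssqs, touched
):
    # persistent zeroed scratch buffers; only touched cells are reset,
    # so the cost is O(n + occupied cells), not O(3^K)
    n = X.shape[0]
    k = snp_idx.shape[0]
    nt = 0
    for i in range(n):
        c = 0
        for j in range(k):
            c = c * 3 + X[i, snp_idx[j]]
        if counts[c] == 0:
            touched[nt] = c
            nt += 1
        counts[c] += 1
        sums[c] += y[i]
        ssqs[c] += y2[i]
    n1 = 0
    s1 = 0.0
    ss1 = 0.0
    for t in range(nt):
        c = touched[t]
        if sums[c] > grand_mean * counts[c]:
            n1 += counts[c]
            s1 += sums[c]
            ss1 += ssqs[c]
        counts[c] = 0
        sums[c] = 0.0
        ssqs[c] = 0.0
    return n1, s1, ss1


_group_moments_nb = (
    _numba.njit(_group_moments_scratch_py, cache=False)
    if _numba is not None
    else None
)


class DatasetStats:
    """Precomputed trait moments shared by all model evaluations on a dataset."""

    def __init__(self, dataset: GenotypeDataset):
        self.genotypes = dataset.genotypes
        # column-contiguous int64 copy: cheap column gathers in the hot path
        self.columns = np.asfortranarray(dataset.genotypes.astype(np.int64))
        # row-contiguous int8 copy for the compiled kernel
        self.rows = np.ascontiguousarray(dataset.genotypes, dtype=np.int8)
        self.y = dataset.phenotype
        self.y2 = self.y * self.y
        self.n = len(self.y)
        self.total_sum = float(self.y.sum())
        self.total_ss = float(self.y2.sum())
        self.grand_mean = self.total_sum / self.n
        self._scratch: tuple | None = None

    def scratch(self, max_k: int = DEFAULT_MAX_K) -> tuple:
        n_cells = 3**max_k
        if self._scratch is None or len(self._scratch[0]) < n_cells:
            self._scratch = (
                np.zeros(n_cells, dtype=np.int64),
                np.zeros(n_cells, dtype=np.float64),
                np.zeros(n_cells, dtype=np.float64),
                np.zeros(min(self.n, n_cells) + 1, dtype=np.int64),
            )
        return self._scratch


def fast_t(stats: DatasetStats, snps: tuple[int, ...], welch: bool = False) -> tuple[float, bool]:
    """Single-pass QMDR label-and-test for one SNP set (hot path of the search)."""
    if _group_moments_nb is not None:
        snp_idx = np.asarray(snps, dtype=np.int64)
        counts, sums_b, ssqs_b, touched = stats.scratch(max(len(snps), DEFAULT_MAX_K))
        n1, s1, ss1 = _group_moments_nb(
            stats.rows, snp_idx, stats.y, stats.y2, stats.grand_mean,
            counts, sums_b, ssqs_b, touched,
        )
        n1 = float(n1)
    else:
        X = stats.columns
        codes = X[:, snps[0]].copy()
        for s in snps[1:]:
            codes *= 3
            codes += X[:, s]
        n_cells = 3 ** len(snps)
        counts = np.bincount(codes, minlength=n_cells)
        sums = np.bincount(codes, weights=stats.y, minlength=n_cells)
        occupied = np.flatnonzero(counts)
        # cell mean > grand mean, without per-cell division
        high_occ = sums[occupied] > stats.grand_mean * counts[occupied]
        if n_cells <= 729:
            ssq = np.bincount(codes, weights=stats.y2, minlength=n_cells)
            hi = occupied[high_occ]
            n1 = float(counts[hi].sum())
            s1 = float(sums[hi].sum())
            ss1 = float(ssq[hi].sum())
        else:
            # wide tables: per-sample mask beats another full-width bincount
            high = np.zeros(n_cells, dtype=bool)
            high[occupied[high_occ]] = True
            mask = high[codes]
            n1 = float(np.count_nonzero(mask))
            s1 = float(stats.y[mask].sum())
            ss1 = float(stats.y2[mask].sum())
    return _pooled_t_from_moments(
        n1, s1, ss1,
        stats.n - n1, stats.total_sum - s1, stats.total_ss - ss1,
        welch=welch,
    )


def score_model(
    dataset: GenotypeDataset,
    snp_indices,
    ek_table,
    max_k: int = DEFAULT_MAX_K,
    welch: bool = False,
    _stats: DatasetStats | None = None,
) -> ModelScore:
    """Score one candidate model on the three search objectives.

    t-statistic from the QMDR kernel; mean interaction information as the
    arithmetic mean of the expert-knowledge gains over all unordered SNP
    pairs in the model (0 for single-SNP models); size = model order K.
    """
    snps = _check_indices(snp_indices, dataset.n_snps, max_k)
    stats = _stats if _stats is not None else DatasetStats(dataset)
    t, valid = fast_t(stats, snps, welch=welch)
    k = len(snps)
    if k == 1:
        mii = 0.0
    else:
        pairs = list(itertools.combinations(snps, 2))
        mii = float(np.mean([ek_table.gain[i, j] for i, j in pairs]))
    return ModelScore(
        t_statistic=t if valid else 0.0,
        mean_interaction_info=mii,
        size=k,
        valid=valid,
    )


def kfold_qmdr_score(
    dataset: GenotypeDataset,
    snp_indices,
    n_folds: int = 10,
    rng: np.random.Generator | None = None,
) -> dict:
    """Post-hoc k-fold QMDR scorer (training/testing t per fold).

    Cross-validation is not part of the evolutionary search — Pareto
    optimization replaces it there — but a fold-wise score remains useful
    for judging a final model's stability.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n = dataset.n_samples
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    train_t, test_t = [], []
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        train = GenotypeDataset(
            dataset.genotypes[mask], dataset.phenotype[mask],
            dataset.snp_ids, dataset.phenotype_kind,
        )
        attr = construct_attribute_quantitative(train, snp_indices)
        train_t.append(t_statistic(attr, train.phenotype))
        # apply the trained cell labels to the held-out fold
        codes_test = _cell_codes(dataset.genotypes[fold], tuple(snp_indices))
        k = len(tuple(snp_indices))
        high_lookup = np.zeros(3**k, dtype=bool)
        for combo, lab in attr.cell_map.items():
            code = sum(g * 3**i for i, g in enumerate(combo))
            high_lookup[code] = lab == HIGH
        y_test = dataset.phenotype[fold]
        m = high_lookup[codes_test]
        y1, y0 = y_test[m], y_test[~m]
        t, _ = _pooled_t_from_moments(
            len(y1), y1.sum(), (y1**2).sum(), len(y0), y0.sum(), (y0**2).sum()
        )
        test_t.append(t)
    return {
        "train_t": train_t,
        "test_t": test_t,
        "mean_test_t": float(np.mean(test_t)),
    }
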