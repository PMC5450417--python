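"""Genotype dataset I/O in plain-text formats.

Two dialects are supported: PLINK additive recode (``.raw``: six metadata
columns ``FID IID PAT MAT SEX PHENOTYPE`` followed by one space-separated
column per SNP) and a tab-separated table with a header row
``sample_id <phenotype> <snp_id> ...``.  Genotypes are coded 0/1/2 as the
number of copies of the major allele; the coding is taken at face value
because the downstream MDR machinery is invariant to allele-label
permutation within a SNP.  Samples with missing genotypes are dropped and
counted — the MDR cell statistics are count-based and assume complete data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLINK_META_COLUMNS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")

__all__ = [
    "GenotypeDataset",
    "TruthSet",
    "DataFormatError",
    "read_dataset",
    "write_dataset",
    "write_results",
    "read_results",
]


class DataFormatError(ValueError):
    """Raised when an input file cannot be parsed into a valid dataset."""


@dataclass
class GenotypeDataset:
    """Samples x SNPs genotype matrix with a phenotype vector.

    Parameters
    ----------
    genotypes : ndarray of shape (n_samples, n_snps)
        Integer matrix with values in {0, 1, 2} (copies of the major allele).
    phenotype : ndarray of shape (n_samples,)
        Continuous trait, or 0/1 endpoint when ``phenotype_kind="binary"``.
    snp_ids : list of str
        Unique identifier per SNP column.
    phenotype_kind : {"quantitative", "binary"}
    n_dropped : int
        Number of sample rows dropped during loading (missing values).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]
    phenotype_kind: str = "quantitative"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.snp_ids = [str(s) for s in self.snp_ids]
        if self.genotypes.ndim != 2:
            raise DataFormatError("genotypes must be a 2-D matrix")
        if self.genotypes.shape[0] != self.phenotype.shape[0]:
            raise DataFormatError(
                f"phenotype length {self.phenotype.shape[0]} != "
                f"{self.genotypes.shape[0]} genotype rows"
            )
        if self.genotypes.shape[1] != len(self.snp_ids):
            raise DataFormatError("snp_ids length must match genotype columns")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise DataFormatError("snp_ids must be unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataFormatError(
                f"genotype value {self.genotypes[i, j]!r} at sample row {i}, "
                f"column '{self.snp_ids[j]}' is not in {{0,1,2}}"
            )
        self.genotypes = self.genotypes.astype(np.int8)
        if self.phenotype_kind not in ("quantitative", "binary"):
            raise DataFormatError(
                f"unknown phenotype_kind {self.phenotype_kind!r}"
            )
        if self.phenotype_kind == "binary" and not np.isin(
            self.phenotype, (0.0, 1.0)
        ).all():
            raise DataFormatError("binary phenotype must contain only 0/1")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class TruthSet:
    """Identifiers of the simulated functional SNPs, grouped by gene."""

    functional_snp_ids: list[str]
    genes: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        flat = [s for pair in self.genes for s in pair]
        if flat != list(self.functional_snp_ids):
            raise ValueError(
                "functional_snp_ids must equal the concatenation of genes"
            )
        if len(set(flat)) != len(flat):
            raise ValueError("duplicate functional SNP ids")


def _infer_kind(values: np.ndarray) -> str:
    return "binary" if np.isin(values, (0.0, 1.0)).all() else "quantitative"


def read_dataset(
    path: str | Path,
    format: str = "tsv",
    phenotype_column: str | None = None,
    phenotype_kind: str | None = None,
) -> GenotypeDataset:
    """Read a genotype dataset from a TSV or PLINK ``.raw`` file.

    Rows with any missing value are dropped; the count is stored in
    ``n_dropped`` and logged.  Genotype codes outside {0,1,2} raise
    :class:`DataFormatError` naming the offending cell.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise DataFormatError(f"cannot parse {path}: {exc}") from exc
        if df.shape[1] < 3:
            raise DataFormatError(
                f"{path}: need sample_id, phenotype and >=1 SNP column"
            )
        pheno_col = phenotype_column or df.columns[1]
        if pheno_col not in df.columns:
            raise DataFormatError(
                f"{path}: phenotype column {pheno_col!r} not found"
            )
        snp_cols = [c for c in df.columns[1:] if c != pheno_col]
    elif format == "plink_raw":
        try:
            df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
        except Exception as exc:  # pragma: no cover
            raise DataFormatError(f"cannot parse {path}: {exc}") from exc
        missing_meta = [c for c in PLINK_META_COLUMNS if c not in df.columns]
        if missing_meta:
            raise DataFormatError(
                f"{path}: not a PLINK .raw file (missing {missing_meta})"
            )
        pheno_col = phenotype_column or "PHENOTYPE"
        if pheno_col not in df.columns:
            raise DataFormatError(
                f"{path}: phenotype column {pheno_col!r} not found"
            )
        snp_cols = [c for c in df.columns if c not in PLINK_META_COLUMNS]
    else:
        raise DataFormatError(f"unknown format {format!r}")

    sub = df[[pheno_col] + snp_cols]
    keep = ~sub.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing values from %s", n_dropped, path)
    sub = sub.loc[keep]
    if sub.empty:
        raise DataFormatError(f"{path}: no complete rows after dropping NAs")

    geno = sub[snp_cols].to_numpy()
    if not np.issubdtype(geno.dtype, np.number):
        raise DataFormatError(f"{path}: non-numeric genotype values")
    if np.any(geno != np.round(geno)):
        bad = np.argwhere(geno != np.round(geno))[0]
        raise DataFormatError(
            f"{path}: non-integer genotype at line {bad[0] + 2}, "
            f"column '{snp_cols[bad[1]]}'"
        )
    geno = geno.astype(np.int64)
    bad_mask = ~np.isin(geno, (0, 1, 2))
    if bad_mask.any():
        i, j = np.argwhere(bad_mask)[0]
        raise DataFormatError(
            f"{path}: genotype value {geno[i, j]} at line {i + 2}, "
            f"column '{snp_cols[j]}' is not in {{0,1,2}}"
        )
    pheno = sub[pheno_col].to_numpy(dtype=float)
    kind = phenotype_kind or _infer_kind(pheno)
    return GenotypeDataset(
        genotypes=geno,
        phenotype=pheno,
        snp_ids=list(snp_cols),
        phenotype_kind=kind,
        n_dropped=n_dropped,
    )


def _truth_path(path: Path) -> Path:
    return path.with_name(path.name + ".truth.json")


def write_dataset(
    dataset: GenotypeDataset,
    truth: TruthSet | None,
    path: str | Path,
    phenotype_name: str = "phenotype",
) -> None:
    """Write a dataset as TSV (plus a JSON truth sidecar when given).

    ``read_dataset(write_dataset(d))`` reproduces genotypes bit-exactly and
    the phenotype to full ``repr`` precision.
    """
    path = Path(path)
    if dataset.n_samples == 0:
        raise DataFormatError("refusing to write an empty dataset")
    width = len(str(dataset.n_samples))
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:0{width}d}" for i in range(dataset.n_samples)],
            phenotype_name: [repr(float(v)) for v in dataset.phenotype],
        }
    )
    for j, sid in enumerate(dataset.snp_ids):
        df[sid] = dataset.genotypes[:, j]
    df.to_csv(path, sep="\t", index=False)
    if truth is not None:
        payload = {
            "functional_snp_ids": list(truth.functional_snp_ids),
            "genes": [list(pair) for pair in truth.genes],
        }
        _truth_path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )


def read_truth(path: str | Path) -> TruthSet:
    """Read the truth sidecar written next to a dataset TSV."""
    path = Path(path)
    sidecar = _truth_path(path) if not path.name.endswith(".truth.json") else path
    payload = json.loads(sidecar.read_text())
    return TruthSet(
        functional_snp_ids=list(payload["functional_snp_ids"]),
        genes=[tuple(pair) for pair in payload["genes"]],
    )


def _model_row(model, snp_ids: list[str] | None) -> dict:
    snps = list(model.snps)
    ids = [snp_ids[i] for i in snps] if snp_ids is not None else [str(i) for i in snps]
    return {
        "snps": ids,
        "t_statistic": model.score.t_statistic,
        "mean_interaction_info": model.score.mean_interaction_info,
        "size": model.score.size,
        "pareto_rank": model.pareto_rank,
    }


def write_results(
    front,
    archive_summary: dict,
    path: str | Path,
    snp_ids: list[str] | None = None,
) -> None:
    """Write a scored model front as JSON plus a flat TSV table.

    ``path`` names the JSON file; a sibling with suffix ``.tsv`` is written
    alongside with one row per model.
    """
    path = Path(path)
    rows = [_model_row(m, snp_ids) for m in front]
    payload = {"models": rows, "summary": archive_summary}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    flat = pd.DataFrame(
        {
            "snps": [",".join(r["snps"]) for r in rows],
            "t_statistic": [repr(float(r["t_statistic"])) for r in rows],
            "mean_interaction_info": [
                repr(float(r["mean_interaction_info"])) for r in rows
            ],
            "size": [r["size"] for r in rows],
            "pareto_rank": [r["pareto_rank"] for r in rows],
        }
    )
    flat.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)


def read_results(path: str | Path) -> dict:
    """Load a results JSON written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
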