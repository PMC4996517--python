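"""Dataset readers/writers and scenario configuration files.

Two on-disk dialects are supported: a plain delimited table (header row,
SNP columns coded 0/1/2 plus one phenotype column) and the PLINK ``.raw``
additive dialect (whitespace-separated, six fixed leading columns
``FID IID PAT MAT SEX PHENOTYPE`` followed by SNP columns).  Missing
genotypes are "NA" (configurable) and are stored internally as -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import Scenario
from .tables import MISSING

PLINK_FIXED_COLUMNS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class Dataset:
    """In-memory genotype/phenotype dataset."""

    genotypes: np.ndarray  # (n, p) int8, -1 for missing
    phenotype: np.ndarray  # length-n class labels or quantitative values
    snp_ids: list
    sample_ids: list
    phenotype_kind: str = "categorical"  # or "quantitative"

    def __post_init__(self):
        n = self.genotypes.shape[0]
        if self.phenotype.shape[0] != n or len(self.sample_ids) != n:
            raise ValueError("row counts disagree between dataset fields")
        if len(self.snp_ids) != self.genotypes.shape[1]:
            raise ValueError("SNP id count disagrees with the genotype matrix")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("SNP ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_classes(self) -> int:
        if self.phenotype_kind != "categorical":
            raise ValueError("quantitative phenotype has no class count")
        return int(np.unique(self.phenotype).size)


def _validate_genotype_frame(g: pd.DataFrame, missing: str) -> np.ndarray:
    values = g.to_numpy(dtype=object)
    out = np.empty(values.shape, dtype=np.int8)
    for (r, c), v in np.ndenumerate(values):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == missing or v == "":
            out[r, c] = MISSING
            continue
        try:
            iv = int(v)
            ok = float(v) == iv and iv in (0, 1, 2)
        except (TypeError, ValueError):
            ok = False
        if not ok:
            raise ValueError(
                f"malformed genotype code {v!r} at row {r}, column {g.columns[c]!r}"
            )
        out[r, c] = iv
    return out


def _phenotype_kind(values: np.ndarray, requested: str | None) -> str:
    if requested in ("categorical", "quantitative"):
        return requested
    if requested not in (None, "auto"):
        raise ValueError("phenotype_kind must be 'categorical', 'quantitative' or 'auto'")
    v = np.asarray(values)
    if v.dtype.kind in "iub" or v.dtype.kind in "OUS":
        return "categorical"
    as_float = v.astype(float)
    return "categorical" if np.allclose(as_float, np.round(as_float)) else "quantitative"


def read_dataset(
    path,
    format: str | None = None,
    phenotype_column: str = "PHENOTYPE",
    sep: str | None = None,
    missing: str = "NA",
    phenotype_kind: str | None = None,
) -> Dataset:
    """Read a delimited-text or PLINK .raw dataset.

    ``format`` is "csv" or "plink_raw"; when omitted it is inferred from
    the file suffix (".raw" vs anything else).  For delimited text ``sep``
    defaults to comma for ".csv" and tab otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "plink_raw" if path.suffix == ".raw" else "csv"
    if format == "plink_raw":
        frame = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        if list(frame.columns[:6]) != PLINK_FIXED_COLUMNS:
            raise ValueError(
                ".raw file must start with the columns " + " ".join(PLINK_FIXED_COLUMNS)
            )
        snp_cols = list(frame.columns[6:])
        if not snp_cols:
            raise ValueError(".raw file contains no SNP columns")
        sample_ids = frame["IID"].tolist()
        pheno_raw = frame["PHENOTYPE"].to_numpy()
    elif format == "csv":
        if sep is None:
            sep = "," if path.suffix == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        if phenotype_column not in frame.columns:
            raise ValueError(f"missing phenotype column {phenotype_column!r}")
        snp_cols = [c for c in frame.columns if c != phenotype_column]
        sample_ids = list(range(len(frame)))
        pheno_raw = frame[phenotype_column].to_numpy()
    else:
        raise ValueError("format must be 'csv' or 'plink_raw'")

    genotypes = _validate_genotype_frame(frame[snp_cols], missing)
    try:
        pheno = pd.to_numeric(pd.Series(pheno_raw)).to_numpy()
    except (ValueError, TypeError):
        pheno = np.asarray(pheno_raw)
    kind = _phenotype_kind(pheno, phenotype_kind)
    if kind == "categorical" and pheno.dtype.kind == "f":
        pheno = pheno.astype(np.int64)
    return Dataset(
        genotypes=genotypes,
        phenotype=pheno,
        snp_ids=snp_cols,
        sample_ids=sample_ids,
        phenotype_kind=kind,
    )


def write_dataset(
    dataset: Dataset,
    path,
    sep: str = ",",
    phenotype_column: str = "PHENOTYPE",
    missing: str = "NA",
) -> None:
    """Write a dataset as delimited text (SNP columns plus phenotype)."""
    g = dataset.genotypes.astype(object)
    g[dataset.genotypes == MISSING] = missing
    frame = pd.DataFrame(g, columns=dataset.snp_ids)
    frame[phenotype_column] = dataset.phenotype
    frame.to_csv(path, sep=sep, index=False)


def load_scenario(path) -> Scenario:
    """Load a YAML scenario description (see `gidscan.evaluate.Scenario`)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("scenario file must contain a mapping")
    return Scenario.from_dict(raw)
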