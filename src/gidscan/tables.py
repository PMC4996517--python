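"""Multi-locus genotype x phenotype contingency tables.

For a combination of k SNPs under additive (minor-allele count) coding,
each sample falls into one of the 3^k multifactor genotype classes. The
table cross-tabulates those classes against the J phenotype classes; all
association measures in :mod:`gidscan.measures` are functions of it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Sentinel for a missing genotype call in integer-coded matrices.
MISSING = -1


class DegeneratePhenotypeError(ValueError):
    """Raised when the phenotype has fewer than two occupied classes."""


@dataclass(frozen=True)
class ContingencyTable:
    """An I x J count matrix ``n_ij`` with genotype rows and phenotype columns.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape (I, J) with total > 0.
    row_labels
        One label per genotype row (multi-locus genotype tuples for tables
        built by :func:`build_contingency_table`).
    col_labels
        One label per phenotype class, in sorted label order.
    n_excluded
        Number of samples dropped for missing genotypes when the table was
        built from raw data.
    """

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()
    n_excluded: int = 0

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("table must contain at least one observation")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        I, J = counts.shape
        if not self.row_labels:
            object.__setattr__(self, "row_labels", tuple(range(I)))
        if not self.col_labels:
            object.__setattr__(self, "col_labels", tuple(range(J)))
        if len(self.row_labels) != I or len(self.col_labels) != J:
            raise ValueError("label lengths do not match the count matrix")

    # -- marginals -----------------------------------------------------
    @property
    def I(self) -> int:  # noqa: E743 - matches the field's I x J convention
        return self.counts.shape[0]

    @property
    def J(self) -> int:
        return self.counts.shape[1]

    @property
    def n(self) -> int:
        """Grand total of the table."""
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def expected(self) -> np.ndarray:
        """Independence-expected counts ``E_ij = n_i. * n_.j / n``."""
        return np.outer(self.row_totals, self.col_totals) / self.n

    def column_index(self, label) -> int:
        try:
            return self.col_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown phenotype class label: {label!r}") from None


def _as_int_genotypes(genotypes) -> np.ndarray:
    """Coerce a genotype matrix to int64 with MISSING for NaN entries."""
    G = np.asarray(genotypes)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (samples x SNPs)")
    if G.dtype.kind == "f":
        G = np.where(np.isnan(G), MISSING, G).astype(np.int64)
    else:
        G = G.astype(np.int64)
    bad = (G != MISSING) & ((G < 0) | (G > 2))
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype code {G[r, c]} at sample {r}, SNP {c}; "
            "expected 0/1/2 or missing"
        )
    return G


def genotype_cell_index(sub: np.ndarray) -> np.ndarray:
    """Mixed-radix (genotype-major) cell index for a (n, k) genotype block.

    A sample with genotypes ``(g_1, ..., g_k)`` maps to
    ``sum_m g_m * 3**(k - m)``, i.e. the first SNP varies slowest.
    """
    k = sub.shape[1]
    weights = 3 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return sub @ weights


def build_contingency_table(
    genotypes,
    combination: Sequence[int],
    classes,
) -> ContingencyTable:
    """Cross-tabulate a k-SNP combination against phenotype classes.

    Samples with a missing genotype at any of the chosen SNPs are excluded
    (listwise per combination); the excluded count is recorded on the table.
    All 3^k genotype rows are retained even when empty so that row indexing
    is stable across SNP combinations.
    """
    G = _as_int_genotypes(genotypes)
    combination = tuple(int(i) for i in combination)
    if len(combination) < 1:
        raise ValueError("combination must contain at least one SNP index")
    if any(i < 0 or i >= G.shape[1] for i in combination):
        raise IndexError(f"SNP index out of range in combination {combination}")

    y = np.asarray(classes)
    if y.shape[0] != G.shape[0]:
        raise ValueError("genotypes and classes must cover the same samples")
    if y.dtype.kind == "f" and np.any(np.isnan(y)):
        raise ValueError("phenotype classes contain NaN (unknown class label)")
    labels, y_codes = np.unique(y, return_inverse=True)
    if labels.size < 2:
        raise DegeneratePhenotypeError(
            "phenotype must have at least two distinct classes"
        )

    k = len(combination)
    sub = G[:, list(combination)]
    keep = np.all(sub != MISSING, axis=1)
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all samples excluded for missing genotypes")

    cells = genotype_cell_index(sub[keep])
    counts = np.zeros((3**k, labels.size), dtype=np.int64)
    np.add.at(counts, (cells, y_codes[keep]), 1)

    row_labels = tuple(itertools.product((0, 1, 2), repeat=k))
    return ContingencyTable(
        counts=counts,
        row_labels=row_labels,
        col_labels=tuple(labels.tolist()),
        n_excluded=n_excluded,
    )
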