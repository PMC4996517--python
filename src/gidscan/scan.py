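"""Exhaustive k-locus GIDS scans with max-statistic permutation inference.

The workflow mirrors the standard multifactor-dimensionality-reduction
scan, with GIDS replacing balanced accuracy so any number of phenotype
classes can be analyzed:

1. for every combination of k SNPs, build the 3^k x J contingency table;
2. score it with GIDS — larger means stronger genomic association;
3. permute the phenotype vector B times, rescore all combinations per
   permutation, and keep each permutation's maximum GIDS.  The collected
   maxima form the null distribution of the scan's best score, so the
   p-values it yields are already adjusted for the multiplicity of the
   exhaustive search.

`GIDSScan` is the model object (data + phenotype coding); `fit` runs one
order and returns a `GIDSScanResults`; `fit_best` compares orders through
their order-specific permutation nulls and returns a `BestModelResults`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import rng_from, seed_sequence
from .measures import compute_gids
from .tables import (
    MISSING,
    DegeneratePhenotypeError,
    _as_int_genotypes,
    build_contingency_table,
    genotype_cell_index,
)

PVALUE_RULES = ("add-one", "plain")


@dataclass(frozen=True)
class NullDistribution:
    """Permutation null of the maximum GIDS over all order-k combinations."""

    order: int
    values: np.ndarray
    seed: object = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("null distribution must hold at least one value")
        object.__setattr__(self, "values", values)

    @property
    def B(self) -> int:
        return self.values.size


def permutation_pvalue(
    observed: float, null: NullDistribution, rule: str = "add-one"
) -> float:
    """P-value of an observed statistic against a max-statistic null.

    ``add-one`` (default) uses (1 + #{null >= observed}) / (B + 1), which
    can never be zero; ``plain`` uses #{null >= observed} / B.  Ties count
    against the observed value in both.
    """
    if rule not in PVALUE_RULES:
        raise ValueError(f"rule must be one of {PVALUE_RULES}")
    r = int(np.sum(null.values >= observed))
    if rule == "add-one":
        return (r + 1) / (null.B + 1)
    return r / null.B


class _OrderPrep:
    """Precomputed per-order state reused across permutations.

    Cell codes, row marginals and (phenotype-class totals being permutation
    invariant) the expected counts and the GIDS denominator are all fixed;
    only the observed cell counts change with the phenotype ordering.
    """

    def __init__(self, G: np.ndarray, y_codes: np.ndarray, J: int, order: int):
        n, p = G.shape
        self.order = order
        self.combos = list(itertools.combinations(range(p), order))
        self.n_cells = 3**order
        C = len(self.combos)
        sub = G[:, np.asarray(self.combos)]  # (n, C, k)
        self.codes = np.ascontiguousarray(
            genotype_cell_index(sub.reshape(-1, order)).reshape(n, C).T
        )  # (C, n)
        width = self.n_cells * J
        self.offsets = (np.arange(C, dtype=np.int64) * width)[:, None]
        row_tot = np.zeros((C, self.n_cells), dtype=np.int64)
        for c in range(C):
            row_tot[c] = np.bincount(self.codes[c], minlength=self.n_cells)
        col_tot = np.bincount(y_codes, minlength=J)
        pj = col_tot / n
        self.denom = float((n * pj * (1.0 - pj)).sum())
        if self.denom <= 0.0:
            raise DegeneratePhenotypeError(
                "phenotype is concentrated in a single class"
            )
        self.expected = row_tot[:, :, None] * (col_tot[None, None, :] / n)
        self.J = J
        self.width = width
        self.n = n

    def gids_all(self, y_codes: np.ndarray) -> np.ndarray:
        """GIDS of every combination for one phenotype ordering."""
        flat = self.codes * self.J + y_codes[None, :] + self.offsets
        counts = np.bincount(
            flat.ravel(), minlength=len(self.combos) * self.width
        ).reshape(len(self.combos), self.n_cells, self.J)
        num = 0.5 * np.abs(counts - self.expected).sum(axis=(1, 2))
        return num / self.denom


class GIDSScan:
    """Exhaustive GIDS interaction scan of a genotype/phenotype dataset.

    Parameters
    ----------
    genotypes
        (n, p) matrix of minor-allele counts in {0, 1, 2}; missing as -1
        or NaN.  Samples with a missing call at a scanned SNP are dropped
        for that combination only.
    phenotype
        Length-n categorical class labels (any sortable dtype, J >= 2).
    snp_ids
        Optional SNP names; defaults to SNP1..SNPp.
    """

    def __init__(self, genotypes, phenotype, snp_ids: Sequence[str] | None = None):
        self.genotypes = _as_int_genotypes(genotypes)
        y = np.asarray(phenotype)
        if y.shape[0] != self.genotypes.shape[0]:
            raise ValueError("genotypes and phenotype must cover the same samples")
        self.class_labels, self._y_codes = np.unique(y, return_inverse=True)
        if self.class_labels.size < 2:
            raise DegeneratePhenotypeError(
                "phenotype must have at least two distinct classes"
            )
        self.phenotype = y
        n, p = self.genotypes.shape
        if snp_ids is None:
            snp_ids = [f"SNP{i + 1}" for i in range(p)]
        if len(set(snp_ids)) != p:
            raise ValueError("SNP ids must be unique and cover every SNP")
        self.snp_ids = list(snp_ids)
        self._has_missing = bool(np.any(self.genotypes == MISSING))

    # -- constructors --------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, phenotype_column: str = "PHENOTYPE"
    ) -> "GIDSScan":
        """Build a scan from a DataFrame of SNP columns plus a class column."""
        if phenotype_column not in frame.columns:
            raise KeyError(f"phenotype column {phenotype_column!r} not found")
        snp_cols = [c for c in frame.columns if c != phenotype_column]
        return cls(
            frame[snp_cols].to_numpy(),
            frame[phenotype_column].to_numpy(),
            snp_ids=snp_cols,
        )

    @classmethod
    def from_quantitative(
        cls,
        genotypes,
        trait,
        n_classes: int,
        z: float | None = None,
        snp_ids: Sequence[str] | None = None,
    ) -> "GIDSScan":
        """Categorize a quantitative trait (equal-area cuts) and build a scan."""
        from .simulate import categorize_trait

        return cls(genotypes, categorize_trait(trait, n_classes, z=z), snp_ids)

    # -- properties ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_classes(self) -> int:
        return self.class_labels.size

    # -- scanning ------------------------------------------------------
    def _gids_exhaustive(self, order: int) -> tuple[list[tuple], np.ndarray]:
        if self._has_missing:
            combos = list(itertools.combinations(range(self.n_snps), order))
            vals = np.array(
                [
                    compute_gids(
                        build_contingency_table(self.genotypes, c, self.phenotype)
                    )
                    for c in combos
                ]
            )
            return combos, vals
        prep = self._prep(order)
        return prep.combos, prep.gids_all(self._y_codes)

    def _prep(self, order: int) -> _OrderPrep:
        return _OrderPrep(self.genotypes, self._y_codes, self.n_classes, order)

    def fit(
        self,
        order: int = 2,
        permutations: int = 0,
        seed=None,
        pvalue_rule: str = "add-one",
    ) -> "GIDSScanResults":
        """Score all C(p, k) combinations; optionally attach permutation p-values.

        With ``permutations=B`` a max-GIDS null of size B is built by
        permuting the phenotype against the fixed genotype rows, and every
        combination receives a p-value against that common null.
        """
        if not 1 <= order <= self.n_snps:
            raise ValueError("order must satisfy 1 <= k <= number of SNPs")
        combos, vals = self._gids_exhaustive(order)
        idx = sorted(range(len(combos)), key=lambda i: (-vals[i], combos[i]))
        combos = [combos[i] for i in idx]
        vals = vals[idx]
        null = None
        pvals = None
        if permutations:
            null = self.permutation_null(order, permutations, seed)
            srt = np.sort(null.values)
            r = null.B - np.searchsorted(srt, vals, side="left")
            if pvalue_rule == "add-one":
                pvals = (r + 1) / (null.B + 1)
            elif pvalue_rule == "plain":
                pvals = r / null.B
            else:
                raise ValueError(f"pvalue_rule must be one of {PVALUE_RULES}")
        return GIDSScanResults(
            model=self,
            order=order,
            combinations=combos,
            gids=vals,
            null=null,
            p_values=pvals,
            pvalue_rule=pvalue_rule,
        )

    def permutation_null(self, order: int, permutations: int, seed=None) -> NullDistribution:
        """Null distribution of the order-k max GIDS under phenotype permutation.

        Each iteration draws its own RNG from a spawned child of the master
        seed, so results are reproducible and independent of any execution
        order of the iterations.
        """
        if permutations < 1:
            raise ValueError("at least one permutation is required")
        children = seed_sequence(seed).spawn(permutations)
        n = self.n_samples
        maxima = np.empty(permutations)
        if self._has_missing:
            for b, child in enumerate(children):
                perm = np.random.default_rng(child).permutation(n)
                shuffled = self.phenotype[perm]
                vals = [
                    compute_gids(
                        build_contingency_table(self.genotypes, c, shuffled)
                    )
                    for c in itertools.combinations(range(self.n_snps), order)
                ]
                maxima[b] = max(vals)
        else:
            prep = self._prep(order)
            y = self._y_codes
            for b, child in enumerate(children):
                perm = np.random.default_rng(child).permutation(n)
                maxima[b] = prep.gids_all(y[perm]).max()
        return NullDistribution(order=order, values=maxima, seed=seed)

    def fit_best(
        self,
        orders: Sequence[int] = (1, 2, 3, 4),
        permutations: int = 1000,
        seed=None,
        pvalue_rule: str = "add-one",
    ) -> "BestModelResults":
        """Fit each order with its own permutation null and pick the best model.

        The null is order-specific (the max over C(p, k) combinations
        depends on k) so p-values are comparable across orders; the best
        model is the top combination with the smallest p-value, ties broken
        by smaller order, then larger GIDS.
        """
        if not orders:
            raise ValueError("at least one interaction order is required")
        children = seed_sequence(seed).spawn(len(orders))
        per_order = {}
        for k, child in zip(orders, children):
            per_order[k] = self.fit(
                order=k, permutations=permutations, seed=child, pvalue_rule=pvalue_rule
            )
        best_order = min(
            per_order,
            key=lambda k: (
                per_order[k].frame["p_value"].iloc[0],
                k,
                -per_order[k].frame["GIDS"].iloc[0],
            ),
        )
        return BestModelResults(per_order=per_order, best_order=best_order)


@dataclass
class GIDSScanResults:
    """Ranked results of one exhaustive order-k scan."""

    model: GIDSScan
    order: int
    combinations: list
    gids: np.ndarray
    null: NullDistribution | None = None
    p_values: np.ndarray | None = None
    pvalue_rule: str = "add-one"
    frame: pd.DataFrame = field(init=False)

    def __post_init__(self):
        cols = {
            f"SNP{m + 1}": [self.model.snp_ids[c[m]] for c in self.combinations]
            for m in range(self.order)
        }
        cols["GIDS"] = self.gids
        cols["rank"] = np.arange(1, len(self.combinations) + 1)
        if self.p_values is not None:
            cols["p_value"] = self.p_values
        self.frame = pd.DataFrame(cols)

    @property
    def best(self) -> pd.Series:
        """The top-ranked combination."""
        return self.frame.iloc[0]

    @property
    def best_combination(self) -> tuple:
        return tuple(self.combinations[0])

    def pvalue_of(self, observed: float) -> float:
        if self.null is None:
            raise ValueError("no permutation null attached; fit with permutations>0")
        return permutation_pvalue(observed, self.null, self.pvalue_rule)

    def to_tsv(self, path) -> None:
        """Write the ranked table (SNP1..SNPk, GIDS, rank, p_value) as TSV."""
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self, top: int = 10) -> str:
        lines = [
            f"GIDS interaction scan  (order k={self.order}, "
            f"{len(self.combinations)} combinations)",
            f"samples: {self.model.n_samples}   SNPs: {self.model.n_snps}   "
            f"phenotype classes: {self.model.n_classes}",
        ]
        if self.null is not None:
            lines.append(
                f"permutations: {self.null.B}   p-value rule: {self.pvalue_rule}"
            )
        lines.append(self.frame.head(top).to_string(index=False))
        return "\n".join(lines)

    def plot_null(self, ax=None):
        """Histogram of the max-GIDS permutation null with the observed best."""
        if self.null is None:
            raise ValueError("no permutation null attached; fit with permutations>0")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null.values, bins=30, color="0.7", edgecolor="0.4")
        ax.axvline(self.gids[0], color="crimson", label=f"observed max={self.gids[0]:.4f}")
        ax.set_xlabel(f"max GIDS over order-{self.order} combinations")
        ax.set_ylabel("permutations")
        ax.legend()
        return ax


@dataclass
class BestModelResults:
    """Top model per interaction order plus the overall best by p-value."""

    per_order: dict
    best_order: int

    @property
    def best(self) -> pd.Series:
        return self.per_order[self.best_order].best

    @property
    def best_combination(self) -> tuple:
        return self.per_order[self.best_order].best_combination

    def summary(self) -> str:
        lines = ["Best-model selection across interaction orders"]
        for k in sorted(self.per_order):
            res = self.per_order[k]
            row = res.best
            snps = ",".join(str(row[f"SNP{m + 1}"]) for m in range(k))
            mark = "  <- best" if k == self.best_order else ""
            lines.append(
                f"  order {k}: ({snps}; GIDS={row['GIDS']:.4f}, "
                f"p={row['p_value']:.4g}){mark}"
            )
        return "\n".join(lines)


# -- functional surface ------------------------------------------------


def scan_order(genotypes, classes, order: int, snp_ids=None) -> GIDSScanResults:
    """Exhaustively score all order-k combinations by GIDS (no p-values)."""
    return GIDSScan(genotypes, classes, snp_ids).fit(order=order)


def permutation_null(genotypes, classes, order, permutations, seed=None) -> NullDistribution:
    """Max-GIDS permutation null for an order-k scan of a dataset."""
    return GIDSScan(genotypes, classes).permutation_null(order, permutations, seed)


def select_best_model(
    genotypes, classes, orders=(1, 2, 3, 4), permutations=1000, seed=None
) -> BestModelResults:
    """Scan several orders and select the best model by permutation p-value."""
    return GIDSScan(genotypes, classes).fit_best(orders, permutations, seed)
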