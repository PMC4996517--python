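"""Association measures on genotype x phenotype contingency tables.

The central measure is the generalized index of dissimilarity (GIDS)

    GIDS = (1/2) * sum_j sum_i |n_ij - E_ij| / sum_j n * P_.j * (1 - P_.j)

with E_ij = n_i. * n_.j / n and P_.j = n_.j / n.  The denominator is the
maximum attainable numerator, so GIDS lies in [0, 1]: 0 at exact
independence, 1 when every genotype row contains a single phenotype class.
For two phenotype classes GIDS reduces to the classic index of
dissimilarity IDS = (1/2) sum_i |n_i1/n_.1 - n_i2/n_.2|, which in turn is
analytically tied to the balanced accuracy of the conventional high/low
risk classifier by IDS = 2*BA - 1.  GIDS therefore generalizes balanced
accuracy to any number of outcome classes without ever assigning risk
statuses.  A Pearson chi-square statistic is provided as the natural
deviation-from-independence comparator.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .tables import ContingencyTable, DegeneratePhenotypeError

HIGH = "HIGH"
LOW = "LOW"


class ConfusionCounts(NamedTuple):
    """Pooled 2x2 confusion counts of the high/low-risk classifier."""

    TP: int
    TN: int
    FP: int
    FN: int


def gids_numerator_denominator(counts: np.ndarray) -> tuple[float, float]:
    """Return the GIDS numerator (1/2)Σ|n−E| and denominator Σ n·P(1−P)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    p = col / n
    denom = float((n * p * (1.0 - p)).sum())
    expected = np.outer(row, col) / n
    num = 0.5 * float(np.abs(counts - expected).sum())
    return num, denom


def compute_gids(table: ContingencyTable) -> float:
    """Generalized index of dissimilarity of a table, in [0, 1]."""
    num, denom = gids_numerator_denominator(table.counts)
    if denom <= 0.0:
        raise DegeneratePhenotypeError(
            "all observations fall in a single phenotype class; "
            "GIDS denominator is zero"
        )
    return num / denom


def _require_two_columns(table: ContingencyTable) -> None:
    if table.J != 2:
        raise ValueError(f"a two-class table is required, got J={table.J}")
    if np.any(table.col_totals == 0):
        raise DegeneratePhenotypeError("both phenotype class totals must be > 0")


def compute_ids(table: ContingencyTable) -> float:
    """Index of dissimilarity (1/2)Σ_i |n_i1/n_.1 − n_i2/n_.2| for J=2."""
    _require_two_columns(table)
    n1, n2 = table.col_totals
    props = table.counts / np.array([n1, n2], dtype=float)
    return 0.5 * float(np.abs(props[:, 0] - props[:, 1]).sum())


def _case_control_columns(table: ContingencyTable, case_column=None) -> tuple[int, int]:
    _require_two_columns(table)
    if case_column is None:
        case = 0  # by convention the first sorted label is the case class
    else:
        case = table.column_index(case_column)
    return case, 1 - case


def assign_risk_status(table: ContingencyTable, case_column=None) -> np.ndarray:
    """HIGH/LOW risk per genotype row.

    Row i is HIGH iff n_i^case / n_i^control >= n^case / n^control,
    evaluated as the integer cross-product
    n_i^case * n^control >= n_i^control * n^case (exact, and defined when
    a row has no controls). Ties go to HIGH.
    """
    case, ctrl = _case_control_columns(table, case_column)
    n_case, n_ctrl = table.col_totals[case], table.col_totals[ctrl]
    high = table.counts[:, case] * n_ctrl >= table.counts[:, ctrl] * n_case
    return np.where(high, HIGH, LOW)


def confusion_counts(
    table: ContingencyTable, risk: np.ndarray, case_column=None
) -> ConfusionCounts:
    """Pool rows by risk status into TP/TN/FP/FN.

    Cases in HIGH rows are true positives, controls in LOW rows true
    negatives; conserves TP+FN = n^case and TN+FP = n^control.
    """
    case, ctrl = _case_control_columns(table, case_column)
    risk = np.asarray(risk)
    if risk.shape[0] != table.I:
        raise ValueError("risk vector must have one status per genotype row")
    high = risk == HIGH
    return ConfusionCounts(
        TP=int(table.counts[high, case].sum()),
        TN=int(table.counts[~high, ctrl].sum()),
        FP=int(table.counts[high, ctrl].sum()),
        FN=int(table.counts[~high, case].sum()),
    )


def compute_ba(table: ContingencyTable, case_column=None) -> float:
    """Balanced accuracy (sensitivity + specificity)/2 of the risk classifier.

    Under the conventional "ties to HIGH" risk rule this lies in [0.5, 1]
    and satisfies IDS = 2*BA - 1.
    """
    risk = assign_risk_status(table, case_column)
    cm = confusion_counts(table, risk, case_column)
    sens = cm.TP / (cm.TP + cm.FN)
    spec = cm.TN / (cm.TN + cm.FP)
    return 0.5 * (sens + spec)


def chi_square_statistic(table: ContingencyTable) -> float:
    """Pearson statistic Σ (n_ij − E_ij)²/E_ij; cells with E_ij=0 contribute 0."""
    counts = table.counts.astype(float)
    expected = table.expected
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return float(terms.sum())
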