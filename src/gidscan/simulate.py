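"""Synthetic genotype/phenotype generators for the simulation studies.

Two study designs are emulated:

* a categorical design — independent Hardy-Weinberg SNPs, one causal pair,
  and a 3-class phenotype drawn from a per-genotype-cell penetrance table
  derived from class prevalences and odds ratios;
* a quantitative design — a trait drawn per causal-pair genotype cell from
  either N(f_ij, sigma_L^2) when the cell mean f_ij lies below the
  population average f-bar, or the symmetric two-component mixture
  (N(f_ij - alpha, sigma_H^2) + N(f_ij + alpha, sigma_H^2))/2 otherwise,
  then categorized into J equal-area classes by mean/SD thresholds.

Null datasets use the same machinery with a constant penetrance (or
all-equal f table), making the phenotype independent of every SNP.  A
composite-phenotype helper and the 9-class JNC7 blood-pressure
classification are included because multi-class analysis of composite
traits is the method's main use case.

What these generators deliberately do NOT emulate: linkage disequilibrium
between SNPs, covariates, and population structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import rng_from, seed_sequence
from .tables import _as_int_genotypes

DEFAULT_PREVALENCE = (0.3, 0.4, 0.3)

#: Equal-area categorization multipliers: J=3 uses mean +/- 0.43 SD,
#: J=4 uses mean - 0.67 SD, mean, mean + 0.67 SD.
DEFAULT_Z = {2: None, 3: 0.43, 4: 0.67}

BP_LABELS = (
    "normal",
    "prehypertension",
    "hypertension",
    "prehypertension",
    "prehypertension",
    "hypertension",
    "hypertension",
    "hypertension",
    "hypertension",
)


# -- genotypes ---------------------------------------------------------


def simulate_genotypes(n: int, p: int, mafs, seed=None) -> np.ndarray:
    """Independent SNPs with genotype ~ Binomial(2, MAF) (Hardy-Weinberg).

    ``mafs`` is a scalar or length-p sequence of minor allele frequencies
    in (0, 0.5].
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be positive")
    mafs = np.broadcast_to(np.asarray(mafs, dtype=float), (p,))
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    rng = rng_from(seed)
    return rng.binomial(2, mafs, size=(n, p)).astype(np.int8)


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """P(genotype = 0, 1, 2) under Hardy-Weinberg with the given MAF."""
    q = 1.0 - maf
    return np.array([q * q, 2 * q * maf, maf * maf])


def genotype_cell_probs(mafs: Sequence[float]) -> np.ndarray:
    """Joint probabilities of the 3^k multifactor cells for independent SNPs.

    Cell order is mixed-radix genotype-major, matching the contingency
    table row order.
    """
    probs = np.array([1.0])
    for maf in mafs:
        probs = np.outer(probs, hwe_genotype_probs(maf)).ravel()
    return probs


# -- categorical design ------------------------------------------------


@dataclass(frozen=True)
class CategoricalPenetrance:
    """Per-genotype-cell phenotype distribution p_{j|i} for a k-SNP effect."""

    table: np.ndarray  # (3^k, J) rows summing to 1
    prevalence: np.ndarray  # length-J target marginal class frequencies

    def __post_init__(self):
        table = np.asarray(self.table, dtype=float)
        prevalence = np.asarray(self.prevalence, dtype=float)
        if table.ndim != 2 or table.shape[1] != prevalence.size:
            raise ValueError("penetrance table and prevalence disagree on J")
        if np.any(table < 0) or np.any(table > 1):
            raise ValueError("penetrance entries must lie in [0, 1]")
        if not np.allclose(table.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each penetrance row must sum to 1")
        k = round(np.log(table.shape[0]) / np.log(3))
        if 3**k != table.shape[0]:
            raise ValueError("penetrance table must have 3^k rows")
        object.__setattr__(self, "table", table)
        object.__setattr__(self, "prevalence", prevalence)

    @property
    def k(self) -> int:
        return round(np.log(self.table.shape[0]) / np.log(3))

    @property
    def J(self) -> int:
        return self.table.shape[1]

    def achieved_prevalence(self, mafs: Sequence[float]) -> np.ndarray:
        """Marginal class frequencies Σ_i P(genotype i) p_{j|i} under HWE."""
        return genotype_cell_probs(mafs) @ self.table


def penetrance_from_odds(
    prevalence,
    odds_ratios,
    mafs: Sequence[float] | None = None,
    ipf: bool = False,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> CategoricalPenetrance:
    """Turn class prevalences and per-cell odds ratios into a penetrance table.

    For cell i and class j the unnormalized weight is
    ``w_ij = OR_ij * v_j`` and the penetrance is the row-normalized weight
    (a multinomial-logit enrichment of the prevalence).  Cells with all
    OR = 1 recover the prevalence exactly; a diverging OR drives the cell
    to an indicator of that class; and for J = 2 the construction solves
    the odds-ratio relation p/(1-p) = OR * v_1/v_2 exactly.  With
    ``ipf=True`` (requires ``mafs``) an iterative proportional fitting
    pass rescales column weights until the HWE-weighted marginal class
    frequencies match ``prevalence`` within ``tol``.
    """
    v = np.asarray(prevalence, dtype=float)
    if not np.isclose(v.sum(), 1.0, atol=1e-8):
        raise ValueError("prevalence must sum to 1")
    OR = np.asarray(odds_ratios, dtype=float)
    if np.any(~np.isfinite(OR)) or np.any(OR <= 0):
        raise ValueError("odds ratios must be finite and positive")
    w = OR * v
    if np.any(~np.isfinite(w)):
        raise ValueError("non-finite penetrance weights")
    table = w / w.sum(axis=1, keepdims=True)
    if ipf:
        if mafs is None:
            raise ValueError("ipf=True requires the target MAFs")
        cell_p = genotype_cell_probs(mafs)
        for _ in range(max_iter):
            achieved = cell_p @ table
            if np.max(np.abs(achieved - v)) < tol:
                break
            w = table * (v / achieved)
            table = w / w.sum(axis=1, keepdims=True)
    return CategoricalPenetrance(table=table, prevalence=v)


def simulate_categorical_phenotype(
    genotypes, causal: Sequence[int], penetrance: CategoricalPenetrance, seed=None
) -> np.ndarray:
    """Draw class labels 1..J from the causal cells' penetrance rows.

    Non-causal SNPs never influence the phenotype.
    """
    G = _as_int_genotypes(genotypes)
    causal = tuple(causal)
    if len(causal) != penetrance.k:
        raise ValueError(
            f"penetrance is for k={penetrance.k} loci, causal set has {len(causal)}"
        )
    from .tables import genotype_cell_index

    cells = genotype_cell_index(G[:, list(causal)])
    cum = np.cumsum(penetrance.table, axis=1)
    u = rng_from(seed).random(G.shape[0])
    return 1 + (u[:, None] > cum[cells]).sum(axis=1).astype(np.int64)


# -- quantitative design -----------------------------------------------


@dataclass(frozen=True)
class QuantPenetranceModel:
    """Mean-parameter table f_ij plus noise parameters for the mixture trait.

    ``fbar_mode`` selects how the population average f-bar that splits the
    low/high branches is computed: "weighted" (default) uses the
    HWE-genotype-frequency-weighted mean of f under ``mafs``; "unweighted"
    uses the plain 9-cell average.
    """

    f: np.ndarray  # (3, 3) cell means, rows = SNP1 genotype, cols = SNP2
    sigma_L: float
    sigma_H: float
    alpha: float
    mafs: tuple
    fbar_mode: str = "weighted"

    def __post_init__(self):
        f = np.asarray(self.f, dtype=float)
        if f.shape != (3, 3):
            raise ValueError("f must be a 3x3 cell-mean table")
        if self.sigma_L <= 0 or self.sigma_H <= 0:
            raise ValueError("sigma_L and sigma_H must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.fbar_mode not in ("weighted", "unweighted"):
            raise ValueError("fbar_mode must be 'weighted' or 'unweighted'")
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "mafs", tuple(float(m) for m in self.mafs))

    @property
    def cell_probs(self) -> np.ndarray:
        """(3, 3) HWE joint genotype probabilities of the causal pair."""
        return np.outer(
            hwe_genotype_probs(self.mafs[0]), hwe_genotype_probs(self.mafs[1])
        )

    @property
    def fbar(self) -> float:
        if self.fbar_mode == "weighted":
            return float((self.cell_probs * self.f).sum())
        return float(self.f.mean())

    @property
    def high_branch(self) -> np.ndarray:
        """(3, 3) boolean mask of cells drawn from the mixture (f_ij >= f-bar)."""
        return self.f >= self.fbar

    def cell_variances(self) -> np.ndarray:
        """Within-cell trait variance: sigma_L^2 low branch, sigma_H^2+alpha^2 high."""
        return np.where(
            self.high_branch, self.sigma_H**2 + self.alpha**2, self.sigma_L**2
        )

    def heritability(self) -> float:
        """Var_G / (Var_G + Var_E) with Var_G the variance of cell means."""
        w = self.cell_probs
        var_g = float((w * (self.f - (w * self.f).sum()) ** 2).sum())
        var_e = float((w * self.cell_variances()).sum())
        return var_g / (var_g + var_e)


def model_from_heritability(
    pattern,
    heritability: float,
    sigma_L: float = 1.0,
    sigma_H: float = 1.0,
    alpha: float = 0.4,
    mafs: Sequence[float] = (0.2, 0.2),
    fbar_mode: str = "weighted",
) -> QuantPenetranceModel:
    """Scale a 3x3 effect pattern so the model hits a target heritability.

    The pattern is centered at its genotype-frequency-weighted mean and
    multiplied by the constant c solving
    ``c^2 Var(pattern) / (c^2 Var(pattern) + Var_E) = h2``; centering keeps
    branch membership (f_ij vs f-bar) identical for every c > 0, so Var_E
    is fixed and the equation is exact.
    """
    if not 0 < heritability < 1:
        raise ValueError("heritability must lie strictly between 0 and 1")
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != (3, 3):
        raise ValueError("pattern must be 3x3")
    probe = QuantPenetranceModel(
        f=pattern, sigma_L=sigma_L, sigma_H=sigma_H, alpha=alpha,
        mafs=tuple(mafs), fbar_mode=fbar_mode,
    )
    w = probe.cell_probs
    centered = pattern - (w * pattern).sum() if fbar_mode == "weighted" else (
        pattern - pattern.mean()
    )
    var_pattern = float((w * centered**2).sum())
    if var_pattern <= 0:
        raise ValueError("pattern has no genetic variance")
    centered_model = QuantPenetranceModel(
        f=centered, sigma_L=sigma_L, sigma_H=sigma_H, alpha=alpha,
        mafs=tuple(mafs), fbar_mode=fbar_mode,
    )
    var_e = float((w * centered_model.cell_variances()).sum())
    c = np.sqrt(heritability / (1.0 - heritability) * var_e / var_pattern)
    return QuantPenetranceModel(
        f=c * centered, sigma_L=sigma_L, sigma_H=sigma_H, alpha=alpha,
        mafs=tuple(mafs), fbar_mode=fbar_mode,
    )


def simulate_quantitative_phenotype(
    genotypes, causal: Sequence[int], model: QuantPenetranceModel, seed=None
) -> np.ndarray:
    """Draw the mixture trait per sample from its causal-pair genotype cell."""
    G = _as_int_genotypes(genotypes)
    i, j = (int(c) for c in causal)
    g1, g2 = G[:, i], G[:, j]
    f = model.f[g1, g2]
    high = model.high_branch[g1, g2]
    rng = rng_from(seed)
    n = G.shape[0]
    y = np.empty(n)
    y[~high] = f[~high] + rng.normal(0.0, model.sigma_L, size=int((~high).sum()))
    n_high = int(high.sum())
    signs = rng.integers(0, 2, size=n_high) * 2 - 1
    y[high] = (
        f[high] + signs * model.alpha + rng.normal(0.0, model.sigma_H, size=n_high)
    )
    return y


# -- trait categorization ----------------------------------------------


@dataclass(frozen=True)
class CategorizationRule:
    """Equal-area cut rule: J classes from mean/SD-based thresholds."""

    J: int
    z: float | None = None

    def __post_init__(self):
        if self.J not in (2, 3, 4):
            raise ValueError("J must be 2, 3 or 4")
        if self.z is None:
            object.__setattr__(self, "z", DEFAULT_Z[self.J])

    def thresholds(self, mu: float, sigma: float) -> np.ndarray:
        if self.J == 2:
            return np.array([mu])
        if self.J == 3:
            return np.array([mu - self.z * sigma, mu + self.z * sigma])
        return np.array([mu - self.z * sigma, mu, mu + self.z * sigma])


def categorize_trait(y, rule_or_J, z: float | None = None) -> np.ndarray:
    """Cut a quantitative trait into J classes labelled 1..J.

    Thresholds come from the trait's own mean and SD: (mu) for J=2,
    (mu - z sigma, mu + z sigma) with z=0.43 for J=3, and
    (mu - z sigma, mu, mu + z sigma) with z=0.67 for J=4 — equal-area cuts
    of a Normal trait.  A value exactly at a threshold joins the upper
    class.
    """
    rule = rule_or_J if isinstance(rule_or_J, CategorizationRule) else (
        CategorizationRule(int(rule_or_J), z)
    )
    y = np.asarray(y, dtype=float)
    mu = float(y.mean())
    sigma = float(y.std(ddof=1)) if y.size > 1 else 0.0
    if sigma <= 0:
        raise ValueError("trait is degenerate (zero standard deviation)")
    th = rule.thresholds(mu, sigma)
    return 1 + np.searchsorted(th, y, side="right").astype(np.int64)


# -- null datasets -----------------------------------------------------


def simulate_null_dataset(
    n: int,
    p: int,
    mafs,
    trait_kind: str = "quantitative",
    J: int | None = None,
    prevalence=None,
    sigma_L: float = 1.0,
    sigma_H: float = 1.0,
    alpha: float = 0.4,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes plus a phenotype independent of every SNP.

    The phenotype follows the regular generators with a constant
    penetrance table (categorical) or an all-equal f table (quantitative
    mixture — every cell sits on the high branch), so it carries no signal
    by construction.  The quantitative trait is returned uncategorized.
    """
    seq = seed_sequence(seed)
    g_seed, y_seed = seq.spawn(2)
    G = simulate_genotypes(n, p, mafs, seed=g_seed)
    if trait_kind == "quantitative":
        mafs_arr = np.broadcast_to(np.asarray(mafs, dtype=float), (p,))
        model = QuantPenetranceModel(
            f=np.zeros((3, 3)), sigma_L=sigma_L, sigma_H=sigma_H, alpha=alpha,
            mafs=(float(mafs_arr[0]), float(mafs_arr[1])),
        )
        y = simulate_quantitative_phenotype(G, (0, 1), model, seed=y_seed)
        return G, y
    if trait_kind == "categorical":
        if J is None and prevalence is None:
            raise ValueError("categorical null needs J or an explicit prevalence")
        if prevalence is None:
            prevalence = np.full(J, 1.0 / J)
        prevalence = np.asarray(prevalence, dtype=float)
        table = np.tile(prevalence, (9, 1))
        pen = CategoricalPenetrance(table=table, prevalence=prevalence)
        y = simulate_categorical_phenotype(G, (0, 1), pen, seed=y_seed)
        return G, y
    raise ValueError("trait_kind must be 'quantitative' or 'categorical'")


# -- blood pressure & composite phenotypes ------------------------------


def classify_blood_pressure(sbp, dbp):
    """JNC7 9-class composite of systolic and diastolic blood pressure.

    SBP bands <120 / [120, 140) / >=140 mmHg and DBP bands <80 / [80, 90)
    / >=90 mmHg combine row-major into outcome classes 1..9, each carrying
    a normal / prehypertension / hypertension label.
    Accepts scalars or arrays; returns (class, label) matching the input
    shape.
    """
    sbp_a = np.asarray(sbp, dtype=float)
    dbp_a = np.asarray(dbp, dtype=float)
    if np.any(~np.isfinite(sbp_a)) or np.any(~np.isfinite(dbp_a)):
        raise ValueError("blood pressures must be finite")
    if np.any(sbp_a <= 0) or np.any(dbp_a <= 0):
        raise ValueError("blood pressures must be positive")
    sband = np.digitize(sbp_a, [120.0, 140.0])
    dband = np.digitize(dbp_a, [80.0, 90.0])
    classes = 3 * sband + dband + 1
    labels = np.asarray(BP_LABELS)[classes - 1]
    if np.isscalar(sbp) and np.isscalar(dbp):
        return int(classes), str(labels)
    return classes.astype(np.int64), labels


def compose_phenotypes(class_vectors: Sequence, n_classes: Sequence[int] | None = None) -> np.ndarray:
    """Fuse several categorical phenotypes into one composite class vector.

    Component classes must be integer labels 1..J_m; the composite class
    is the row-major position in the Cartesian product of the component
    class sets (first component varies slowest), labelled 1..prod(J_m).
    ``n_classes`` overrides the per-component class counts (default: the
    maximum observed label).
    """
    if len(class_vectors) == 0:
        raise ValueError("at least one phenotype component is required")
    vecs = [np.asarray(v, dtype=np.int64) for v in class_vectors]
    lengths = {v.shape[0] for v in vecs}
    if len(lengths) != 1:
        raise ValueError("phenotype components must have equal lengths")
    if any(v.min() < 1 for v in vecs):
        raise ValueError("class labels must be integers starting at 1")
    if n_classes is None:
        n_classes = [int(v.max()) for v in vecs]
    composite = np.zeros_like(vecs[0])
    for v, J in zip(vecs, n_classes):
        if v.max() > J:
            raise ValueError("observed class label exceeds the stated class count")
        composite = composite * J + (v - 1)
    return composite + 1


# -- shipped study models ----------------------------------------------


def checkerboard_odds(strength: float = 5.0) -> np.ndarray:
    """9x3 odds-ratio table with a pure two-way interaction pattern.

    Cells with even genotype-sum (i + j) favour class 1 with the given
    odds ratio, odd cells favour class 3; class 2 is neutral everywhere.
    Marginal single-SNP effects cancel at MAF 0.5, making the causal
    signal genuinely interactive.
    """
    OR = np.ones((9, 3))
    for i in range(3):
        for j in range(3):
            cell = 3 * i + j
            if (i + j) % 2 == 0:
                OR[cell, 0] = strength
            else:
                OR[cell, 2] = strength
    return OR


def strong_three_class_model(
    strength: float = 5.0, prevalence=DEFAULT_PREVALENCE
) -> CategoricalPenetrance:
    """A shipped strong-effect 3-class two-way interaction penetrance model."""
    return penetrance_from_odds(prevalence, checkerboard_odds(strength))


def interpolated_three_class_model(
    t: float, strength: float = 5.0, prevalence=DEFAULT_PREVALENCE
) -> CategoricalPenetrance:
    """Interpolate the shipped model from null (t=0) to full effect (t=1).

    Uses OR^t so t=0 is exactly the no-association model and the effect
    grows monotonically with t.
    """
    return penetrance_from_odds(prevalence, checkerboard_odds(strength) ** t)


def xor_pattern() -> np.ndarray:
    """3x3 exclusive-or effect pattern for the quantitative design."""
    return np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
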