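# Methods

## The measure

For a combination of k SNPs under additive coding (minor-allele counts 0/1/2),
each sample falls into one of I = 3^k multifactor genotype classes. Crossing
these with the J phenotype classes gives a contingency table with counts
n_ij, marginals n_i., n_.j, total n, independence-expected counts
E_ij = n_i. n_.j / n and class shares P_.j = n_.j / n. The generalized
index of dissimilarity is

    GIDS = (1/2) Σ_j Σ_i |n_ij − E_ij|  /  Σ_j n P_.j (1 − P_.j).

The denominator is the largest value the numerator can attain, so GIDS lies
in [0, 1]; it is 0 exactly when every cell equals its expected count and 1
when every genotype row contains a single phenotype class. For J = 2 the
expression reduces algebraically to the classic index of dissimilarity
IDS = (1/2) Σ_i |n_i1/n_.1 − n_i2/n_.2|, and IDS in turn equals 2·BA − 1,
where BA is the balanced accuracy of the conventional high/low-risk
classifier (row i is high-risk iff n_i^case/n_i^control ≥ n^case/n^control).
GIDS is therefore a generalization of balanced accuracy that needs no risk
statuses and no thresholds between outcome classes, which is what makes
phenotypes with arbitrary J — including composite multi-trait classes such
as the 9-class JNC7 blood-pressure states — analyzable.

Numerical notes:

* The risk rule is evaluated as the integer cross-product
  n_i^case · n^control ≥ n_i^control · n^case — exact, and defined when a
  row has no controls. Ties go to HIGH. The equivalence IDS = 2·BA − 1 holds
  exactly under this rule and is enforced to 1e-12 in the tests.
* Empty genotype rows contribute |0 − 0| = 0 to the numerator and are kept
  in the table, so row indexing is stable across SNP combinations.
* Phenotype columns are ordered by sorted class label; GIDS is invariant
  under row and column permutations and under uniform scaling of counts
  (property-tested).
* The χ² comparator is the raw Pearson statistic Σ (n_ij − E_ij)²/E_ij with
  E_ij = 0 cells contributing 0 (they force n_ij = 0); it is used for
  ranking, not converted to a p-value.
* Samples with a missing genotype at a scanned SNP are excluded listwise
  per combination; the excluded count is recorded on the table.

## The scan and its inference

`GIDSScan.fit(order=k)` scores all C(p, k) combinations and ranks them by
GIDS (descending; ties broken by lexicographically smallest SNP tuple for
determinism). With `permutations=B` the phenotype vector is permuted against
the fixed genotype rows B times; each permutation rescans all combinations
and contributes its maximum GIDS to the null distribution. Using the
maximum makes the resulting p-values family-wise adjusted for the
exhaustive search. The p-value of an observed value g is
(1 + #{null ≥ g}) / (B + 1) by default — never zero, ties counting against
the observation; the plain #{null ≥ g}/B estimator is available via
`pvalue_rule="plain"`.

`fit_best(orders=...)` builds one null per order (the distribution of the
maximum depends on k) and selects the overall best model by smallest
p-value, ties broken by smaller order, then larger GIDS. Each permutation
iteration derives its RNG from a spawned child of the master seed, so
results are reproducible and independent of execution order.

The scan is evaluated through a vectorized kernel: per order it precomputes
each combination's mixed-radix cell codes, row marginals and (class totals
being permutation-invariant) the expected counts and denominator once, so a
permutation costs one shared bincount over all combinations. The kernel is
verified against per-pair table construction to 1e-12; datasets with
missing genotypes fall back to the per-combination path, which handles
listwise exclusion exactly.

## Synthetic data

The generators define the study conditions; their defaults are the
conditions used by the test suite and the acceptance script.

**Genotypes.** Independent SNPs, genotype ~ Binomial(2, MAF) (Hardy-
Weinberg). Defaults per design: n = 400 samples, p = 20 SNPs; MAF 0.5 for
the categorical design, 0.2/0.4 for the quantitative and null designs.

**Categorical design.** A single causal pair and a 3-class phenotype with
prevalence v = (0.3, 0.4, 0.3). Per-cell odds ratios are converted to
penetrances by the multinomial-logit weighting p_{j|i} ∝ OR_ij · v_j: all
OR = 1 recovers the prevalence exactly, a diverging OR drives the cell to
an indicator, and for J = 2 this solves the odds-ratio relation
p/(1−p) = OR·v_1/v_2 exactly. An optional iterative-proportional-fitting
pass rescales columns until the HWE-weighted marginal class frequencies
match the target prevalence (tolerance 1e-6). This conversion is our own
construction — the original study designs state only that penetrances are
"determined" by prevalence and odds ratios, and their specific OR sets live
in another publication's supplement — so the shipped models are
representative rather than replicas. The shipped strong model puts OR = 5
on class 1 in checkerboard cells (genotype-sum even) and OR = 5 on class 3
in the complementary cells: at MAF 0.5 the single-SNP marginal effects
cancel, making the signal purely interactive. Consequence worth knowing:
two- and three-locus hit ratios are high while the single-locus hit ratio
sits near chance — a pure-epistasis stress test, deliberately harder for
marginal methods than mixed-effect models would be. An OR^t family
(t ∈ [0, 1]) interpolates from exact null to full strength for
monotonicity checks.

**Quantitative design.** For a sample in causal cell (i, j) with cell mean
f_ij, the trait is N(f_ij, σ_L²) when f_ij < f̄ and the symmetric mixture
(N(f_ij − α, σ_H²) + N(f_ij + α, σ_H²))/2 otherwise (mixture mean f_ij,
variance σ_H² + α²). f̄ is the genotype-frequency-weighted mean of f by
default (the population mean the branch comparison implies); the
unweighted 9-cell mean is available via `fbar_mode`. Defaults α = 0.4,
σ_L = σ_H = 1.0 (the studied grids span σ ∈ {0.8, 1.0, 1.2}). Rather than
shipping the external catalogue of 70 penetrance tables, a parametric
generator centers a user-chosen 3×3 pattern (default: XOR checkerboard)
and scales it so that heritability Var_G/(Var_G + Var_E) — Var_G the
genotype-frequency-weighted variance of cell means, Var_E the weighted
within-cell variance — hits a target in (0, 1); centering preserves branch
membership, making the scaling exact. The grid values 0.01, 0.02/0.025,
0.05, 0.1, 0.2, 0.3, 0.4 are all representable.

**Trait categorization.** J classes from the trait's own sample mean μ and
SD σ (ddof = 1): thresholds (μ) for J = 2, (μ − 0.43σ, μ + 0.43σ) for
J = 3, (μ − 0.67σ, μ, μ + 0.67σ) for J = 4 — equal-area cuts of a Normal
trait (z = 0.43 and 0.67 are the ⅓ and ¼ Normal quantile offsets). A value
exactly at a threshold joins the upper class, consistently across J.

**Null datasets.** The quantitative design with an all-equal (zero) f
table: every cell sits on the mixture branch, so the trait is
(N(−α, σ_H²) + N(+α, σ_H²))/2 independent of every SNP. Null replicates
cycle MAF through 0.2 and 0.4, mirroring the averaging over MAF conditions
in the original type-I-error summary.

**What the generators do not emulate** — and hence what passing tests do
not establish about real data: linkage disequilibrium between SNPs (real
scans contend with correlated combinations), covariates and population
stratification (real null distributions can be miscalibrated by structure),
genotyping error and informative missingness, and real effect-size
spectra. Tests demonstrate correctness and calibration under the stated
generating models, not robustness to these complications.

## Evaluation harness

Hit ratios are computed from the top-1 combination per order, set-wise:
two-locus requires the exact causal pair, single-locus accepts either
causal SNP, three-locus accepts any triple containing both. Type-I error is
the fraction of null replicates whose observed max-GIDS p-value is ≤ α.
Rates carry binomial standard errors; per-replicate outcomes are persisted
as JSON-lines for audits.

Problem sizes used by the shipped studies: null calibration at 200
replicates × 200 permutations per J ∈ {2, 3, 4} in the test suite (rates
checked against the exact binomial 99% interval around α = 0.05, and the
p-values against uniformity by a Kolmogorov–Smirnov test at the 0.01
level) and 500 replicates × 200 permutations in the acceptance script, the
larger replicate count tightening the Monte-Carlo error of the reported
rate; power studies at 100 replicates. At the default (r+1)/(B+1) p-value
rule with B = 200, the exact null rejection probability at α = 0.05 is
10/201 ≈ 4.98%, so the calibration checks are centred slightly below 5%.

## Design choices that were genuinely open

* **p-value estimator**: (r+1)/(B+1) chosen as the default because it is a
  valid p-value (never zero and exactly uniform on its support under the
  null); r/B retained as an option since published permutation values are
  often reported that way.
* **Permutation target**: permuting the phenotype vector rather than
  shuffling genotype rows — equivalent for exchangeable samples, cheaper,
  and it preserves the genotype matrix (hence any LD structure a user's
  real data may have).
* **Odds-ratio → penetrance weighting**: p ∝ OR·v (multinomial logit)
  rather than odds-transform-then-normalize; only the former recovers the
  prevalence at OR = 1 and the indicator limit simultaneously.
* **Best-model tie-breaking**: smaller order preferred at equal p-values
  (parsimony), then larger GIDS; within an order, lexicographically
  smallest SNP tuple. All tie rules exist for determinism and are tested.
* **Case-column convention**: for two-class tables the first sorted label
  is treated as the case class by default; BA is invariant to the choice,
  and it is overridable wherever risk statuses surface.

## Known limitations

* The exhaustive scan is O(C(p, k) · (B + 1)); genome-wide p at k ≥ 2 is
  out of reach of this in-memory implementation (by design — the package
  targets candidate-set analyses and simulation studies).
* GIDS requires a categorical phenotype; quantitative traits must be
  categorized first, and the equal-area rule shipped here is a convention,
  not a recommendation for any particular real phenotype.
* Penetrance-from-odds is one construction among several; studies needing
  a specific published penetrance table should pass it directly.
* Cross-validation is intentionally absent: model selection is by
  max-statistic permutation p-values across orders.
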