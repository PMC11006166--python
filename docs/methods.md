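# Methods

## Model families

A genotype G of an n-gene system is the subset of genes carrying the active
allele; its mean phenotype is decomposed as

    mean(G) = β₀ + Σ_{T ⊆ active(G), 1 ≤ |T| ≤ K} w(family, |T|, |active(G)|) · β_T

with β₀ referenced to the all-mutant genotype (the most disrupted state) and
K the model's maximum interaction order.  The weights are

| family    | w(k, m)                    |
|-----------|----------------------------|
| additive  | 1                          |
| nr        | 1 if k = 1, else 1/C(m, k) |
| averaging | 1/C(m, k)                  |

The averaging weight is equivalently defined by the recursion w(m, m) = 1,
w(k, m) = ((m − k)/m) · w(k, m − 1): each coefficient is the deviation of its
genotype from the average of the genotypes with one gene fewer.  The closed
form and the recursion are verified against each other exactly (as rationals)
for all k ≤ m ≤ 10 in the test suite.  Weights are computed as
`fractions.Fraction` and converted to float once per matrix, so large
binomial denominators introduce no accumulation error.

Genotypes and terms are ordered canonically by (subset size, lexicographic
position in the universe).  Under this order the full-model design matrix
over the 2^n-genotype lattice is lower-triangular with unit diagonal, so

- exact solving (one mean per genotype) is a forward triangular substitution
  (`scipy.linalg.solve_triangular`), not a generic inversion;
- invertibility is structural, for every family and every n ≤ 16 (the
  enforced universe cap, chosen because the dense 2^n lattice must enumerate
  in memory; published examples use n ≤ 7).

Two independent closed forms serve as oracles for the solver and never share
its code path: Möbius inversion coef(S) = Σ_{T⊆S} (−1)^{|S|−|T|} mean(T) for
the additive family, and the direct deviation-from-average definition for the
averaging family.

Mutant-allele coding (effects of knockouts referenced to the wild type) is
implemented as complement relabelling of the mean table rather than a fourth
model family: the wild-type coding is the interpretable one, and the
relabelling (an involution) gives the conventional coefficients exactly.

## Genotype text dialects

Both field notations are parsed: *full* (one character per gene, case = allele
state, "ABc") and *omission* (active genes only, "AB"; "-" for all-mutant).
Auto-detection treats a token as full iff it has one character per gene
matching the universe order case-insensitively.  A full-length permutation of
the universe in the wrong order is rejected rather than silently reinterpreted
as an omission list; an explicit dialect override is available in the API and
CLI for corpora that use unordered active-gene lists.

## Statistical fitting

`MultiGeneModel.fit()` estimates the coefficients from replicated long-format
data by least squares on the observation-expanded design (rows of the lattice
matrix repeated per observation).  The three full models are
reparameterizations of the genotype cell-means model, so their fitted values
and residuals coincide; the families differ in the decomposition only.
Inference:

- residual df = N − p (p = number of fixed-effect columns); CIs are
  estimate ± t(0.975, df) · SE; the same N − p convention is used for the
  mixed model as a documented approximation of containment df — at small
  group counts this can make mixed-model CIs slightly narrow, a known
  limitation;
- the Holm (step-down, FWER) family is all non-intercept terms of one fit;
  the Benjamini-Hochberg (step-up, FDR) family is the per-gene set of
  background contrasts within one screen; neither spans datasets;
- with zero residual df, estimates are returned and all inference fields are
  NaN (flagged via `inference_available`).

Nested random intercepts (e.g. replicate/flat/pot) are fitted by REML
(statsmodels `MixedLM`; REML for unbiased variance components) with the top
level as the grouping factor and deeper levels as variance components whose
labels are qualified by their ancestry to keep the nesting strict.  A
variance component estimated on the boundary (zero variance) commonly makes
the optimizer report non-convergence; since the fixed-effect estimates remain
valid in that case, it is surfaced as a warning rather than an error, and
estimation only fails hard on non-finite estimates (with an explicit
opt-in fall-back to OLS).  Zero-variance hierarchies reproduce the OLS
estimates to ~1e−6, which the tests assert.

Missing genotypes are fatal for full-model fits (the lattice must be
complete) and permitted with a warning for reduced models as long as the
truncated design keeps full column rank.

### Treatment contrasts

With a two-level treatment column the modeled quantity per genotype is the
within-genotype treatment contrast (treated − control; the control level is
named in the configuration, and the sign convention means a positive
coefficient is a larger response under treatment).  The design retains one
nuisance cell-mean column per genotype and applies the model's design row
times the treated indicator, so the model coefficients decompose the
genotype-specific treatment effects.  This is a documented interpretation of
combining per-genotype treatment interactions with the lattice design, not a
verbatim reconstruction of any particular historical analysis script.

### Gene screening and bundling

Screening fits the cell-means model once (with random effects and/or
treatment structure if declared) and t-tests, for each gene g and each of the
2^(n−1) backgrounds B not containing g, the difference mean(B ∪ {g}) − mean(B)
using the coefficient covariance and residual df.  The per-gene p-values are
BH-adjusted; a gene is dropped iff none falls below α = 0.05.  Screening runs
once before model choice (re-screening after each removal is possible but not
the default).  A dropped gene is *bundled* away: every genotype is relabeled
over the reduced universe, all observations retained — an explicitly lossy,
irreversible relabelling.

Note the null the screen tests: a gene is "uninvolved" when adding it never
moves a genotype mean, i.e. when all its terms vanish in the **additive**
parameterization.  (A gene with zero *averaging* coefficients still changes
means, because its presence reweights the other terms.)  The synthetic
null-gene datasets in the tests are therefore generated from additive-family
coefficient vectors.

## Synthetic data generator

`generate_replicated_data` emulates a replicated combinatorial-knockout
experiment: each top-level replicate contains every genotype once, laid out
in flats of 8 pots (one genotype per pot), with optional multiple
measurements per pot, Gaussian nested random intercepts per declared level,
Gaussian residual noise, an optional two-level treatment observed in every
pot, and an optional per-observation dropout that produces the unbalanced
replication the mixed model exists for (never dropping a genotype
completely).  Defaults — residual sd 0.5, 3 replicates, random-effect sds of
0.3/0.2/0.1 for replicate/flat/pot — are phenotype-scale noise magnitudes
typical of log-scale bacterial-count data, a fraction of the 1–2 unit
coefficient sizes used in the recovery experiments.  What the generator does
*not* emulate: non-Gaussian or heteroscedastic noise, crossed (non-nested)
design factors, genotyping errors, or missing lattice cells; passing tests
therefore demonstrate correctness of the estimators under the declared
Gaussian nested model, not robustness beyond it.  With one observation per
pot the pot variance is confounded with the residual — the realistic
situation; the variance-recovery tests use two observations per pot or fewer
levels.

## Monte-Carlo stability study

The uniform-random study draws, per repeat, one mean per genotype i.i.d. from
U(low, high) in canonical genotype order from a single seeded generator
(bit-reproducible), solves each requested family on the *same* draws (so the
1-gene effect samples are identical across families — their formulas
coincide), and summarises each non-intercept term's distribution by
quartiles.  Whiskers (1.5·IQR) are computed for plotting only; all statistics
use quartiles.  Standard conditions are n = 7, 10,000 repeats, U(1, 10).

Expected behaviour, used as acceptance checks: the additive order-m
coefficient is a ±-signed sum of 2^m uniforms, so its variance is 2^m·v with
v = (high−low)²/12 and its IQR grows as 1.349·√(2^m v); the order-1 effect is
a difference of two uniforms (symmetric triangular, IQR = 2·range·(1−1/√2)).
The ratio of the 7-gene-interaction IQR to the mean 1-gene IQR is therefore
≈ 7.5, and simulation reproduces it within a few percent.  The averaging
order-m coefficient has variance v(1 + 1/m), nearly flat in m, giving a
max/min IQR ratio below 2 across orders.  Whether "phenotype range" in the
companion several-times-the-range comparison means high − low (9) or the
upper bound (10) is ambiguous; theory gives ≈ 4.4 against range 9, and the
package exposes `iqr_ratio(..., vs_range=True)` (using high − low) rather
than forcing a particular round number.

## Problem sizes and numerical choices

The test suite and acceptance script use n ≤ 7 lattices, 10,000-repeat
studies, and Monte-Carlo batches of 40–500 datasets for coverage, bias,
screening-power and reduction-sensitivity experiments — sizes at which each
experiment's Monte-Carlo error is well below the effect being asserted while
the whole suite runs in well under a minute of pure computation.  Exact
identities are asserted at 1e−9/1e−10; cross-family fitted-value equality at
1e−8; OLS/mixed degenerate agreement at 1e−6 (iterative REML).  Coverage
bands ([0.90, 0.98] for a nominal 0.95) and screening rates (≥ 90% null-gene
drop; keep-rate consistency with BH at 0.05) are binomial bands at the stated
batch sizes.

## Known limitations

- NR weighting of 1-gene terms follows the printed 3-gene expansion (weight
  1 at every genotype order); extending NR beyond that convention is out of
  scope.
- No dominance/heterozygosity, no multi-allelic genes, no crossed random
  effects, no non-Gaussian responses.
- Reproducing published biological coefficient values for the 4-gene
  immune-signalling dataset requires that external raw dataset; the CLI can
  fit it when supplied, but nothing here depends on it.
- The saturating node rule in the network module is a generic bound, offered
  for experimentation with nonlinear mechanisms; the chemical-equilibrium
  analysis that motivates saturation is not reproduced.
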