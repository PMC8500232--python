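# Methods

`scentsel` analyses geographic variation and phenotypic selection on
hyperdiverse, strongly zero-inflated floral-scent matrices — the kind of
data produced by GC/MS surveys of inflorescence volatiles, where several
hundred compounds are quantified per individual and most compounds are
absent (non-detects) from most samples.  This note documents the models and
procedures, the tunable parameters that matter, the synthetic-data
generator, and the numerical and design choices.

## Data model and deterministic transforms

A study is a samples x compounds amount matrix (absolute emission,
ng inflorescence⁻¹ h⁻¹), per-sample metadata (population, region, sample
type), a compound-descriptor table (Kováts retention index, compound
class), and per-individual fruit counts as the female-fitness proxy.

* **Compound filter.** A compound is retained when it occurs (nonzero) in
  at least `min_occurrence` inflorescence samples (default 4, i.e. "more
  than three") and never occurs, at any amount, in a leaf or ambient-air
  control.  The filter is idempotent and preserves column order.
* **Relative amounts** are percent of each sample's total emission; rows
  sum to 100 exactly (to 1e-9).
* **Fruit set** is 100·fruits/flowers per individual; **relative fruit
  set** divides each individual's fruit count by its population's mean
  fruit count, zero-fruit individuals included, so each population's mean
  relative fitness is exactly 1.
* **z-transform** standardises trait columns to mean 0 and sample
  (n−1) standard deviation 1; selection gradients are therefore in units
  of trait standard deviations, and estimates are invariant to positive
  affine changes of the raw measurement scale.

## Distance-based geographic statistics

* **Distances.** Bray–Curtis dissimilarity Σ|x−y|/Σ(x+y) on absolute or
  relative profiles (a semimetric: the triangle inequality is not
  asserted), and |x−y| on univariate summaries (total emission,
  richness).
* **PERMANOVA.** The distance matrix is Gower-centred,
  G = (I−11′/n)(−D²/2)(I−11′/n), and partitioned sequentially (Type I)
  over region and population-nested-in-region using projection matrices;
  for a term with projection difference H the sum of squares is tr(HG).
  The pseudo-F for each term uses the full-model residual mean square.
  p-values are (1 + #{F* ≥ F})/(1 + n_perm) under free row permutation
  (default; within-region restricted permutation is available).  With a
  single factor and Euclidean distances on univariate data the pseudo-F
  reduces exactly to the classical one-way ANOVA F.  An exhaustive mode
  enumerates all distinct label assignments for small single-factor
  designs and returns the exact tail fraction.
* **Mantel test.** Spearman rank correlation of the condensed upper
  triangles; permutation permutes one matrix's rows and columns jointly.
* **CAP / db-RDA.** Principal coordinates of the dissimilarity matrix
  (axes with negative eigenvalues are dropped, not corrected); the
  coordinates are regressed on centred group indicators and the
  constrained axes are eigenvectors of the fitted cross-product.
  Compound vectors are Pearson correlations of each compound with the
  first two constrained axes; compounds with max |r| above 0.5 and a
  Benjamini–Hochberg adjusted p below 0.05 (adjustment across all
  compounds in one ordination) are flagged.
* **Random-forest distinctness.** Classification OOB error (percent) on
  group labels (defaults ntree = 9999, mtry = 17, clamped with a warning
  when mtry exceeds the compound count); importance is mean decrease in
  impurity by default, permutation importance optional.
* **Univariate tests.** Mann–Whitney U (normal approximation) for
  two-region compound contrasts; nested fixed-effects ANOVA for fruit
  set, computed by the same sequential projection partition (region df
  a−1, population df b−a, residual df n−b) with analytic F p-values.
  The projection route is used because a naive nested-interaction
  formula parameterisation over-counts the nested term's degrees of
  freedom in rank-deficient dummy codings.

## Non-detect bias simulation and the eligibility gate

Zero inflation biases regression coefficients toward zero: a compound
detected in few samples carries almost no usable signal.  Rather than
modelling censoring, the pipeline gates compounds by a simulation:

For each detection rate r on a grid (default 0.05…1.0 in steps of 0.05),
`n_rep` studies are simulated.  A latent log-normal focal emission (moments
matched to the template matrix's typical nonzero column) drives continuous
latent fitness w = 1 + effect·z(latent) + ε (the pre-binomial form, so the
measured bias is attributable to non-detects, not count noise).  The
*observed* focal column keeps each sample's emission with probability r and
records zero otherwise; the remaining columns are noise traits resampled
from the template's per-column detection rates and log-moments.  The
elastic net (CV-minimum penalty, so penalty shrinkage stays small relative
to the attenuation being measured) is fitted to the observed matrix and
the focal coefficient recorded.  Reported per grid point: bias
(mean estimate − planted effect), RMSE, and the exactly-zero fraction.
The true |bias| is non-increasing in r (full detection recovers the
effect up to shrinkage; at r → 0 the observed trait is uninformative and
the estimate collapses to zero, so bias → −effect); the Monte-Carlo curve
is made monotone by a running maximum from high to low rates before
gating, so eligibility is monotone in detection rate by construction.

A compound is **eligible** for selection analyses when its observed
detection rate maps (linear interpolation on the grid) to
|bias|/effect ≤ `max_relative_bias` (default 0.5).  The verdict table
records every compound's detection rate, interpolated relative bias, and
decision.

## Pre-selection of fitness-correlated volatiles

Because compounds far outnumber samples, gradients are estimated only on
pre-selected candidates:

* **Elastic net** (`ElasticNetSelector`): penalised linear regression of
  relative fitness on the z-scored eligible compounds (plus total
  emission as an ordinary candidate), mixing L1 and L2 penalties
  (`l1_ratio` default 0.5).  The penalty is chosen by k-fold
  cross-validation (default 10 folds, seeded shuffle).  The default rule
  takes the strongest penalty within one standard error of the CV
  minimum: on wide matrices (n ≈ 60, p ≈ 90) the CV-minimum rule
  carries a median of ~15 spurious selections per fit while the 1-SE
  rule keeps the median below 5 at equal power for moderate effects —
  an operating characteristic the package's acceptance suite measures.
  The CV-minimum rule remains available (`lambda_rule="min"`) and is
  used inside the bias simulation, where minimal shrinkage matters more
  than sparsity.
* **Boruta** (`BorutaSelector`): the all-relevant shadow-feature wrapper
  for non-linear relationships.  Each iteration shuffles every column
  into a shadow copy, fits a random-forest regressor to the doubled
  matrix, and scores a hit for features whose impurity importance
  strictly exceeds the maximum shadow importance (the original
  algorithm's criterion).  Accumulated hits are judged by two-sided
  binomial tests against 0.5 at `alpha_level` (default 0.01); features
  undecided after `max_iter` iterations remain tentative — they are
  never coerced.
* The two candidate lists stay separate: elastic-net selections feed the
  linear (β) model, Boruta confirmations the quadratic (γ) model, with
  the overlap reported.

## Selection gradients

Directional gradients β and quadratic gradients γ are partial regression
coefficients of population-relative fitness on z-scored traits (OLS).
Quadratic models retain the linear terms of the same traits (standard
practice), centre the squared terms, and report γ as exactly twice the
fitted squared-term coefficient, with the SE doubled, so γ measures the
curvature of the individual selection surface.

* **Collinearity.** Variance inflation factors VIF_j = 1/(1−R²_j) are
  computed per term; while any VIF exceeds a threshold (first the strong
  threshold 10, then the moderate threshold 5), the most strongly
  correlated pair of offending main effects is *replaced* by its
  standardised product (interaction) term and the model refit, each
  substitution logged.  Replacing (rather than adding to) the main
  effects treats the merged pair as one selected signal; keeping main
  effects is a configuration alternative.  Non-convergence within the
  round budget returns the best model with a warning.
* **Outliers.** Cook's distances are computed for every sample; samples
  above the flag rule (default 4/n) are reported, samples above the
  exclusion rule (default D > 1) are dropped once and the model refit.
  On clean data both steps are identity transformations.
* Significance is at raw p < 0.05 per term, with no multiple-testing
  correction across gradient terms.

## Synthetic-study generator

The generator reproduces the statistical structure the pipeline assumes,
with full ground truth for recovery tests:

* **Emissions** follow a hurdle model: amount = Bernoulli(p_c) ×
  LogNormal(μ_c + log m·[south], σ_c).  Detection probabilities default
  to p_c = U^1.94, putting ~70% of compounds below 50% detection;
  expected per-sample richness is Σ p_c and is exposed for tuning.  The
  southern region multiplier m defaults to 3 (a 3-fold emission
  difference).  Positive dependence between compounds comes from one
  shared per-sample log-scale factor with loading √ρ (default ρ = 0.3 —
  a deliberately simple structure chosen to exercise the VIF machinery;
  real between-compound correlation is not characterised by the study
  design the generator mimics).
* **Fitness**: latent w = 1 + Σβ_c z_c + ½Σγ_c z_c² + ε with Gaussian
  noise (default sd 0.5, putting the latent R² of typical planted
  surfaces in the 0.5–0.7 range of strong empirical selection models);
  fruiting fraction clamp(b·w, 0, 1) with baseline b = 0.4; flowers per
  plant uniform on 30–70; fruits binomial.  Default sizes mirror two
  focal populations of 43 and 68 samples with ~90 candidate compounds.
* **Nulls**: the same design with β = γ = 0 (and m = 1 for a fully
  exchangeable geographic null).
* All randomness flows through `numpy` Generators seeded from the truth
  object; a (truth, seed) pair regenerates a study exactly, and stage
  seeds in the pipeline are derived by hashing the base seed with the
  stage name, so disabling one stage never shifts another's stream.

**What the generator does not emulate:** compositional constraints among
compounds, population-specific detection probabilities, temporal or
environmental covariates, spatial autocorrelation, and measurement error
in peak integration.  Passing recovery tests therefore show the
*statistical machinery* is correct under the assumed hurdle/log-normal
structure, not that the field data meet those assumptions.

### Numerical notes and degenerate inputs

* Residual sums of squares within 1e-10 of zero are treated as exact
  fits; pseudo-F is then infinite and compares correctly against
  permuted statistics.
* Permutation p-values use (1+count)/(1+n_perm), never zero; exhaustive
  enumeration returns the exact tail fraction including the observed
  assignment.
* Constant (all-zero) trait columns are rejected by the strict
  z-transform; the generator's internal standardiser maps them to zero
  (a never-detected compound contributes no selection), and compounds
  absent from a focal population are dropped before selection analyses.
* Negative principal-coordinate eigenvalues are dropped; an additive
  correction is not applied.
* Attenuation near the readout ceiling: when b·w approaches 1 for
  heavy-tailed traits, the clamp compresses the planted linear signal
  and recovered gradients shrink toward zero; recovery contracts are
  therefore evaluated at baselines where the clamp is inactive.

### Problem sizes in the test and acceptance runs

The shipped suites scale replicate counts to desk sizes: 1,000 null
replicates for PERMANOVA type-I error (99 permutations each), 100
replicates for elastic-net recovery, 50 for the Boruta operating
characteristics, 30 seeds for end-to-end gradient recovery at n = 300
(with a bias profile computed once per suite — the detection-rate →
bias mapping is a property of the study design, not of a single draw),
and 500 replicates for the non-detect bias contrast.  Null calibration
of gradient p-values is measured on fixed candidate sets: running OLS
only on compounds a screen already picked for their sample correlation
with fitness conditions on selection, and no correct implementation
rejects at the nominal rate under that conditioning (post-selection
inference is out of scope).
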