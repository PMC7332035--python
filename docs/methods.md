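# Methods

`pondstress` implements a screening procedure for detecting environmental
stressors (pesticide contamination, habitat degradation, invasive species,
macrophyte loss) that reduce the taxonomic richness of freshwater animals
across a set of ponds. The design target is the regime of a typical pond
survey: few sites (tens of ponds), many candidate explanatory variables
(dozens), and count responses.

## Data model

For pond *i* (of *M*), the richness of one animal category is modelled as

    y_i ~ Poisson(Y_i),   ln(Y_i) = α + Σ_k β_k x_{k,i} + r_i,

where the `x_k` are unit-scaled stressor intensities and `r_i ~ N(0, σ²)`
is a pond-level random effect absorbing unmeasured heterogeneity
(overdispersion). Because each pond contributes a single observation per
category, the mixed model is a Poisson–log-normal overdispersion model.
The σ = 0 variant is the ordinary Poisson GLM; both variants enter model
selection side by side.

### Ingest conventions

* Pesticide series: measurements below the compound's detection limit are
  replaced by the detection limit **per measurement**, then the per-pond
  maximum is taken. Substitute-then-max is used because substitution is
  defined on individual concentrations; for a maximum the order only
  matters when all values are censored. Compounds never measured above
  their detection limit anywhere are dropped.
* Repeated water-quality properties are averaged arithmetically (pH
  included — the source protocol averages the reported pH values, not
  hydrogen-ion activity).
* Stressor-oriented transforms: noncoverage = 100 − plant coverage,
  shallowness = (deepest pond's depth) − depth, and ln(dipnet samples) as a
  sampling-effort covariate. The log base is immaterial (an affine rescale
  followed by unit scaling), natural log is used.
* The pond count is data-driven, never hard-coded.
* Category table: 7 base categories (reptiles, fishes, mollusks,
  crustaceans, large insects, small insects, annelids) and 5 composites
  (all-sampled, large animals, small animals, vertebrates, invertebrates).
  Invasive aliens and pest insects are excluded from every response and
  the four invasive species re-enter as binary explanatory variables.

## Variable contraction

With ~48 explanatory variables and ~21 ponds, exhaustive subset selection
is infeasible and collinearity ruins coefficient interpretation. Variables
are therefore z-standardised and grouped by single-linkage connectivity:
two variables are linked when |Pearson r| > 0.52 (strict), and groups are
the connected components. Single linkage is the minimal reading of
"grouped by correlation"; the threshold, axis rule and group structure are
all surfaced in the provenance report so the choice is auditable.

Each multi-member group is replaced by the minimal number of leading
correlation-matrix PCA axes whose cumulative explained variance strictly
exceeds 65%. Axis signs are fixed so the largest-magnitude loading is
positive (PCA signs are arbitrary; the convention makes downstream
coefficient signs reproducible and is noted in reports). Ties in
eigenvalues are resolved in stable eigenvalue order. Finally every
contracted column — singles and axes alike — is rescaled to [0, 1], the
scale the impact formulas assume (observed maximum intensity ≡ 1).

## Model selection

All non-empty subsets of contracted variables are fitted, each as a fixed
and as a mixed model, excluding models with more free parameters than
⌊M/3⌋. Free parameters count the intercept, the K slopes, and σ for mixed
fits (so at M = 21 the cap of 7 admits K ≤ 6 fixed, K ≤ 5 mixed). Whether
σ ought to count against the cap is not observable from the procedure
description; the accounting here is explicit and configurable via `cap`.
The AIC-best admissible fit is the *contracted best model*; the ΔAIC set
collects every admissible fit within C = 2.0 of it.

Exact AIC ties are broken deterministically: fewer free parameters, then
lexicographic variable order, then fixed before mixed. Determinism matters
because the permutation test embeds the whole selection. Fits that fail
(rank deficiency, non-convergence) are excluded from the candidate set
rather than aborting. All fits are evaluated serially; results are
independent of evaluation order by construction.

### Mixed-model estimation

The marginal likelihood integrates each pond's Poisson pmf over its
Gaussian random effect with adaptive (mode-centred, Liu–Pierce)
Gauss–Hermite quadrature, 21 nodes by default; doubling the node count
changes converged log-likelihoods by < 1e-6. Fixed effects and σ are
optimised jointly (L-BFGS-B with an analytic Fisher-identity gradient,
σ bounded below by 0). σ = 0 lies inside the parameter space, so a mixed
fit is never reported with a likelihood below its fixed counterpart; fits
that hit the boundary return σ = 0 exactly and are flagged. The
fixed-effects solver is a damped Newton iteration (relative log-likelihood
tolerance 1e-10) — selection inside permutation resampling performs
millions of small fits, so per-fit overhead is kept minimal; the solver is
cross-checked against statsmodels GLM in the test suite.

## Statistically contributive variables and significance

A variable of the best model is **statistically contributive** when

1. it appears in *every* ΔAIC ≤ 2 model with a consistently signed
   coefficient (the primary screen);
2. its permutation-of-regressor-residuals (PRR) p-value in the best model
   is < 0.05 — the focal column is regressed linearly on the other model
   columns, the residuals are permuted and added back, the Poisson model
   is refitted, and the one-sided p-value counts permuted coefficients at
   or below the observed one;
3. it is retained with the same sign in the *uncontracted* best model
   found by bidirectional stepwise AIC over the original variables,
   initialised from the contracted best model (singles enter as
   themselves; a grouped variable is replaced by its members, greedily by
   marginal AIC if the cap would be exceeded).

Contributive variables then receive a selection-aware one-sided p-value
from the **selection-embedding permutation test**: the focal contracted
column is permuted across ponds B times (B = 1000 at full
resolution; B = 199 in the default screening mode), the *entire
best-subset selection is re-run* on each resampled dataset, and the test
statistic is the focal coefficient in the re-selected best model, defined
as 0 when the variable is not selected. Permuting the focal column (rather
than the response) preserves the joint distribution of the remaining
covariates. p-values use the add-one convention (1 + #{stat ≤ obs})/(1 + B),
so p ∈ [1/(B+1), 1] and the test is exact under exchangeability. A
**significant stressor** is a contributive variable with p < 0.05 and a
negative coefficient. No multiple-testing correction is applied across
variables or categories; family behaviour is a property of the screen
itself and is characterised by the null simulations.

The statistic-when-excluded-is-zero definition and the focal-column
resampling unit are this package's own concrete realisation of
"permutation embedding the model selection"; they are stated here because
the procedure is only defined up to these choices.

### Interactions

When a category has ≥ 2 contributive mains, the candidate set becomes the
mains plus all their pairwise products (products of unit-scaled columns,
rescaled to [0, 1]); best-subset selection is repeated over it with the
same cap. Hierarchy is not enforced — an interaction may be selected
without its mains. The with-interaction model is reported only when its
AIC is no higher than the mains-only best model. Conditions (1)–(2) and
the selection-embedding test are then applied to the interaction terms.

## Impact estimation

With the log link, stressor *j* divides expected richness by
exp(−β_j x_j): the **mean impact** exp(−β_j x̄_j) evaluates this at the
mean observed intensity, the **maximum impact** exp(−β_j) at the worst
pond (intensity 1). Percent loss is 100(1 − 1/impact), rounded to integer
percent only at the reporting layer. Uncertainty is a Wald 95% interval on
the coefficient, mapped through the same exponential. The stressor-free
baseline R = exp(α + Σ_{k∉contributive} β_k x̄_k) sets contributive
stressors to intensity 0 and holds the remaining covariates at their means
(a scalar baseline; which covariates to freeze and where is a modelling
choice, made explicit here). Impacts of multiple stressors are exactly
multiplicative — additive on the log scale — so per-pond combined impacts
are products of the single-stressor factors. Interaction terms are treated
as stressors with their own unit-scaled column.

## Synthetic data generator

The generator emulates the *statistical* structure the analysis assumes,
not pond ecology: Gaussian latent blocks mapped through monotone
transforms to observed scales (log-normal concentrations, clipped
coverages, thresholded invasive presence, ordinal drainage), and Poisson
counts from known coefficients on unit-scaled columns plus a pond-level
random effect. Blocks are equicorrelated by default; a two-tier form
(shared global factor + sub-factors) produces the several-retained-axis
spectrum of a large heterogeneous group, which equicorrelation cannot (its
spectrum has a single dominant axis). Planted maximum impacts of roughly
2–13 match the magnitudes a pond survey of this kind reports.

`pond_survey_fixture` packages 21 ponds × 48 variables — 9 single
variables, one 2-member block, one 37-member two-tier block — with 12
category responses (null categories, main-effect categories, one
interaction-only category; composites are sums of base categories so the
partition identities hold by construction). At 21 ponds, chance
correlations among 48 variables would merge the singles into the large
component for most random draws, so the fixture orthogonalises the block
factors and single variables in-sample (QR): "single variable" *means*
below-threshold correlation with everything else, and the fixture builds
that property in instead of leaving it to luck. With this the contraction
outcome (11 groups → 14 contracted variables; 1 axis for the pair, 4 for
the large group) is stable across fixture seeds. What passing fixture
tests do **not** show: robustness to non-Gaussian dependence, measurement
error, spatial autocorrelation among ponds, or the sampling design of real
field data.

## Problem sizes and numerical choices

* Screening-mode permutation counts default to B = 199; B = 1000
  restores full resolution (`--full-b` in the CLI).
* Operating-characteristic runs (tests and the acceptance script) use
  200 null replicates at M = 21 with 5 covariates and B = 199, and 30
  power replicates at M = 100 with a planted β = −1.5 — sizes chosen so
  the binomial uncertainty of the estimated rates is small relative to
  the bands being checked. These runs generate data with σ = 0 and use
  fixed-effects-only selection: the model class matches the generating
  truth, and embedding mixed fits in every one of the ~40,000 re-selections
  would multiply the cost by two orders of magnitude without changing what
  the check exercises.
* Wald-coverage runs use 300 replicates at M = 200, σ = 0.3, two planted
  stressors (600 intervals).
* Convergence: Newton stops at relative log-likelihood change < 1e-10;
  L-BFGS-B at ftol 1e-12. Mixed-model covariance comes from a central
  finite-difference Hessian of the marginal log-likelihood at the optimum;
  at a σ = 0 boundary the σ row of the covariance is set to zero and the
  fixed-effects block is used.
* Degenerate inputs: constant columns are rejected by name; empty
  measurement series, unknown categories, non-integer or negative counts,
  and missing values raise errors before any computation.

## Known limitations

* The PRR construction and the selection-embedding statistic are this
  package's own concrete definitions; other implementations of the same
  screening idea may resolve the open details (resampling unit, statistic
  when the focal variable is dropped, exact ties) differently.
* The stepwise expansion of grouped variables into members is likewise a
  defined convention (full expansion, greedy under the cap).
* Wald intervals for σ near the boundary are unreliable (the boundary is
  flagged instead).
* The baseline R extrapolates to intensity 0 for all contributive
  stressors jointly; it inherits the caveat that zero intensity need not
  correspond to an attainable pristine state.
* Impacts are not extrapolated beyond the observed [0, 1] intensity range.
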