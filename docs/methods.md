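# Methods

`briefmds` implements the psychometric pipeline used to turn ordinal
household-survey responses — specifically the Brief Model Disability Survey
(Brief MDS) capacity module (11 items, B5002–B5012) and performance module
(12 items, B4001–B4012), each with five ordered response options (0 = no
problem … 4 = extreme problem) — into interval-scaled 0–100 disability
metrics with severity cutoffs.

## The measurement model

The partial credit model (PCM) is the Rasch-family model for ordered
polytomous items.  For person *n* with ability θ_n (logits) and item *i*
with thresholds δ_i1 … δ_im,

P(X_ni = x) = exp(Σ_{k≤x}(θ_n − δ_ik)) / Σ_h exp(Σ_{k≤h}(θ_n − δ_ik)),

with the empty sum zero.  Thresholds are the abilities at which adjacent
categories are equally probable; the item location is the arithmetic mean
of its thresholds (an identity the `ItemParameters` container enforces
exactly).  Equal item discrimination gives raw-score sufficiency: each raw
score on a fixed item set maps to one ability, which is what permits a
published score-to-ability conversion table and the anchored 0–100 metric.

**Assumptions.** One dominant latent dimension per scale; local independence
given θ; ordered category functioning; invariant item functioning across
groups.  Each assumption has a corresponding diagnostic below.

## Estimation

* **Item calibration** is marginal maximum likelihood via EM with
  Gauss–Hermite quadrature (default 49 nodes) over a normal latent ability
  density.  Identification: latent mean fixed at 0, latent SD free.  The
  M-step solves each item's expected-count likelihood with analytic
  gradients (L-BFGS).  Convergence: largest parameter change < 1e-4
  (default), bounded by 500 EM iterations; non-convergence raises an error
  carrying the iteration trace.  CML- or JML-style calibrations differ from
  MML by (approximately) a common shift of the logit scale; comparisons
  against external calibrations should align identifications first, which is
  why recovery experiments remove the common mean shift before computing
  RMSE.
* **Person measurement** defaults to Warm's weighted likelihood estimate
  (WLE), solved by bracketed root finding on the weighted score equation;
  SE = I(θ̂)^{-1/2}.  WLE keeps raw scores 0 and maximum finite, which the
  0–100 rescaling requires (they anchor 0 and 100).  An MLE mode with a
  0.3-score-point extreme-score adjustment is available.  Missing responses
  are treated as not administered: incomplete responders are measured on
  their own completed item set.
* **Degenerate inputs**: constant items and items with never-observed middle
  categories are rejected with an instruction to recode first; persons with
  no responses are excluded and listed.

## Diagnostic loop

The pipeline iterates, per scale, with recoding tried before testlet
formation (the order used in the national analyses; configurable):

1. **Threshold ordering.**  An item is disordered when any δ_{k+1} ≤ δ_k.
   The automatic remediation merges category k (the one squeezed between
   the disordered pair) into category k−1, refits, and repeats until ordered
   or binary.  Strategies are digit strings over the original categories
   ("00122" maps 0,1,2,3,4 → 0,0,1,2,2); manual strategies always override
   the search.  The downward-merge direction is a package choice: published
   analyses report only final strategies, and the final strategy is
   reported, not the path.  Testlet super-items are exempt from automatic
   collapsing: a summed super-item has rare middle categories, its
   disordered thresholds are expected, and published calibrations keep
   testlets at their full category range.
2. **Local dependence.**  Standardized residuals z_ni = (x_ni − E_ni)/√W_ni
   with E and W evaluated at θ̂_n; Pearson correlations over
   pairwise-complete persons; a pair is flagged when r > 0.2 (strict
   inequality, per the criterion's wording).  Flagged pairs are summed into
   testlets (category count = sum of member maxima + 1); a person's testlet
   score is missing if any member is missing, preserving sufficiency of the
   aggregate.
3. **Item fit.**  Outfit = mean squared standardized residual; infit =
   information-weighted version Σ(x−E)²/ΣW; band (0.8, 1.2), above =
   misfit/outlier influence, below = overfit/redundancy (the item adds
   little independent information).  Because E and W are evaluated at an
   ability estimated from the same responses, the classical statistics have
   null expectation ≈ 1 − 1/(number of items), visibly below 1 for an
   11-item scale.  The default therefore deflates the denominator by the
   item's leverage on the person ability, W(1 − W/I_person), which restores
   a null expectation of ≈ 1 and makes the statistics consistent (→ 1 on
   conforming data); `bias_correction=False` restores the classical
   Wright-style form for comparability with legacy software.  Under the
   strongly off-target default population the corrected outfit of the most
   extreme item can still sit near 0.86 — the quadratic approximation is
   poor in the far tail — which is a known limitation, not misfit.
4. **Targeting.**  Mean/SD of all item thresholds vs mean/SD of person
   abilities; the offset (ability − difficulty mean) is identification-
   invariant and quantifies how far the population sits from the scale's
   working range.

## Unidimensionality

Two-step polychoric correlations (marginal thresholds from inverse-normal
cumulative proportions, then per-pair ML over the bivariate-normal ρ via
bounded scalar optimisation; pairwise-complete observations; boundary
estimates clamped to ±0.999 and flagged).  The exploratory bifactor
solution is Schmid–Leiman: principal-axis factoring with iterated
communalities into k oblique group factors (quartimin rotation via
statsmodels), a single higher-order factor over the factor correlations,
then orthogonalisation λ_g = Λγ, λ_s = Λ√(1−γ²).  Numerical choices: the
input matrix is eigenvalue-clipped to PSD at 1e-6 (flagged); with two group
factors the higher-order solution is underdetermined and the equal-loading
convention γ = √r is used; an extracted factor whose *unrotated* loadings
have no salient entry (max |λ| < 0.25) or negligible shared variance
(SS loadings < 0.25) is treated as null and rotation is skipped — on
effectively rank-one data the oblique rotation would otherwise smear the
single substantive factor across columns, and that factor *is* the general
dimension.  (A genuine group factor with three items loading 0.3 has
SS ≈ 0.54; the noise factors of a rank-one 12-item matrix at n = 2,000 sit
near 0.1.)  Verdict: unidimensional iff every item's λ_g ≥ 0.4 (the "loads
high" cutoff is configurable and always reported) and λ_g > λ_s item-wise.
The default group assignment for the capacity scale follows item content
(sensory, mobility/self-care, psychosocial); for arbitrary scales the
fallback is an alternate-halves split, and callers should supply a
substantive grouping.

## Differential item functioning

* **Hybrid ordinal logistic regression** (lordif-style): per item,
  proportional-odds models M0 (θ), M1 (θ + group), M2 (θ + group + θ×group);
  McFadden R² = 1 − ℓ/ℓ_null with ℓ_null the intercepts-only likelihood.
  Flag when R²(M2) − R²(M0) > 0.02 (scope configurable to per-step changes);
  uniform vs non-uniform attribution via M1−M0 vs M2−M1.  Purification
  re-estimates the matching θ from the currently unflagged anchor items and
  repeats until the flagged set stabilises.  The proportional-odds fits use
  an in-package analytic-gradient ML routine (log-spaced cutpoint
  parametrisation, L-BFGS); its log-likelihoods agree with statsmodels'
  OrderedModel to 1e-4, which the test suite checks.
* **Residual ANOVA** (RUMM-style): two-way ANOVA of z on group and ability
  class interval (default 5 equal-count intervals, merged downward when
  cells empty): group main effect = uniform DIF, interaction = non-uniform.
  Bonferroni adjustment across items.
* **Criterion behaviour.**  The 0.02 McFadden criterion is deliberately
  conservative, and ΔR² is asymptotically sample-size-invariant.  Measured
  dose-response under this package's study conditions (6–11 item scales,
  n = 1,000 per group, uniform shift on one item): mean ΔR² ≈ 0.017 at a
  0.6-logit shift (detection ≈ 10–20%), ≈ 0.042 at a 1.0-logit shift
  (detection 100%).  A 0.6-logit uniform shift therefore sits below what
  the 0.02 criterion can flag reliably at any sample size; the residual
  ANOVA detects the same shift with high power.  Null false-flag rates are
  well below 5%.  Detected DIF is reported, never adjusted for by item
  splitting — for disability scales an age gradient is substantively
  expected.
* Age bands are left-exclusive/right-inclusive: (17.5, 39.5], (39.5, 59.5],
  (59.5, 100]; ages outside are excluded with a count.

## Reliability, scoring, severity

PSI = (Var(θ̂) − mean(SE²))/Var(θ̂), floored at 0, computed on the
estimated-ability sample (matching its Cronbach-alpha analogy); > 0.7
suffices for population surveys, > 0.85 for individual use.  Scores are
rescaled 100·(θ − θ_min)/(θ_max − θ_min), anchored at the WLE abilities of
raw score 0 and the maximum, clipped to [0, 100].  Severity: severe cutoff
= mean + 1 SD of the score distribution (the cross-country disaggregation
rule); the mild (mean − 1 SD) and moderate (mean) cutoffs are package
defaults, explicitly not taken from any survey convention, and
configurable.  Degenerate (zero-variance) distributions raise.

## Brief-vs-full comparison

Pearson correlation of paired ability estimates, and OLS of the full-version
score on the brief item responses entered as numeric category codes (dummy
coding by flag); R² is reported as explained variance.  Note the two
published framings differ — regression on brief *items* vs prediction from
brief *ability estimates*; both are available and the item regression is
the default, with the discrepancy surfaced here rather than resolved.

## Synthetic data generator

`generate_brief_mds_dataset` emulates the study conditions: 11-item
capacity and 12-item performance scales with the standard item codes,
five categories, person abilities N(−1.5, 1.3) (strongly off-target, as in
the national implementations where difficulty means sit near +0.25 against
ability means near −1.5), gender and three adult age bands as covariates.
Item locations follow the published Chile calibration spread; threshold
offsets around each location are −1.0, 0.0, +1.0, +2.0 — asymmetric so that
category 0 stays the majority response overall (≈ 57% of all responses at
the defaults) while top categories remain reachable at n ≈ 2,000.  Optional
mechanisms: uniform DIF (constant threshold shift for the focal group),
non-uniform DIF (group discrimination multiplier on θ − δ), local
dependence (the dependent item copies its partner with probability equal to
the configured strength, leaving the partner's marginal untouched), MCAR
missingness.  All randomness flows from the single config seed; identical
configs give identical output.

What the generator does **not** emulate: household sampling design,
clustering or survey weights; informative missingness; response styles
(e.g. extreme responding); cross-country DIF; multidimensional violations
beyond the injected pairwise dependence.  Passing tests on these data
therefore show the algorithms behave correctly under the stated model, not
that any particular real survey satisfies that model.

## Study conditions used by tests and the acceptance script

Chosen once as this package's documented experiment sizes: calibration
oracle checks at 3 items × 3 categories, n = 200; parameter recovery at
n = 2,000 on the 11-item capacity bank with an on-target population (every
category must be observed for its threshold to be estimable; the common
identification shift is removed before RMSE); PSI recovery at n = 2,000
under the off-target defaults; local-dependence power/size at n = 3,000
with 50 replications (10 in the faster acceptance script); DIF power/size
at n = 1,000 per group with 20 replications in the test suite and a
5-replication dose-response (0.6 and 1.0 logits) in the acceptance script;
determinism/idempotence on a 6-item scale with one disordered generating
item at n = 2,000.

## Known limitations

* Exact reproduction of external calibrations (e.g. the national Brief MDS
  tables) requires the original microdata and matching the (unstated)
  estimator of those analyses; MML vs CML calibrations differ by roughly an
  affine map of the logit scale.
* The polychoric estimator assumes latent bivariate normality; heavy
  violation biases ρ̂.
* The Schmid–Leiman solution is exploratory; with a known group structure a
  confirmatory bifactor model would be sharper.
* The 0.02 McFadden ΔR² DIF criterion cannot reliably flag uniform shifts
  much below ~1 logit (see dose-response above); treat it as a screen for
  large DIF and read it alongside the residual ANOVA.
* Unweighted percentages throughout; survey weights are out of scope.
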