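# Methods

## Estimands

Both estimands are average causal effects (ACEs) on the risk-difference
scale for a binary outcome $Y$ and a continuous food-group exposure $A$
measured in g/d.

- **Addition effect**: $E[Y(A + \Delta, \text{rest of diet})] - E[Y(A,
  \text{rest of diet})]$ with $\Delta$ = 100 g/d by default — the effect of
  adding 100 g/d of the exposure on top of the observed diet.
- **Substitution effect**: the difference of two addition effects computed
  from the same fitted model, ACE(exposure) − ACE(substituted food) —
  interpreting an isoweight swap of $\Delta$ g/d. Sign convention, printed
  in every output: positive means replacing the substituted food with the
  exposure raises risk.

Causal interpretation rests on consistency (well-defined 100 g/d shifts),
conditional exchangeability given the measured confounders, positivity, and
no interference. None of these is testable from data; the synthetic
generator is built so they hold by construction, which is what makes
recovery testing meaningful.

## Estimator

1. **Treatment weights.** For a continuous exposure the stabilized weight is
   a ratio of densities, $SW^A = f(A)/f(A\mid L)$. Both densities are
   Gaussian: the numerator uses the marginal mean and SD of $A$; the
   denominator mean is the fitted value of an ordinary least-squares
   regression of $A$ on reference-coded confounder indicators, and its SD is
   that model's residual standard deviation (square root of the usual
   unbiased mean-squared error). The exposure enters the density models in
   raw g/d; densities are scale-covariant, so the choice of unit cancels in
   the ratio. Rows with missing confounders are excluded from model fitting
   and, by default, receive weight 1 with a flag (configurable: drop, or
   marginal-only).
2. **Censoring weights.** $SW^C = P(C=1)/P(C=1\mid L)$ with the denominator
   from a logistic regression fit on the full eligible population; weights
   are attached to followed participants only. Fitted probabilities at the
   0/1 boundary raise an error naming perfect separation as the likely
   cause.
3. **Truncation and combination.** Each weight is truncated at the 99.5th
   percentile, multiplied, and the product truncated again (each component
   step switchable). The percentile uses the lower-order-statistic
   convention (numpy `method="lower"`): the cap is then itself an observed
   weight, which makes truncation exactly idempotent — an interpolated cap
   would shrink on re-application because clipping raises the upper order
   statistics to the cap.
4. **Outcome model.** A weighted binomial GLM (logit link) of the outcome on
   the exposure and all other food groups in 100 g/d units — confounders are
   handled entirely by the weights. An identity-link variant is provided as
   a weighted linear probability model (WLS); a binomial likelihood with an
   identity link is numerically fragile near the probability boundary and
   adds nothing here, since effects are reported via marginal
   standardization either way. Robust (sandwich, HC1) covariance is the
   default; the model-based covariance is also retained.
5. **Marginal standardization.** Predicted probabilities are contrasted
   row by row at shifted and observed intakes and averaged with the analysis
   weights. Under the identity link this collapses exactly to
   $\Delta \cdot \hat\beta$ (and $\Delta(\hat\beta_{exp} - \hat\beta_{food})$
   for substitution), which the tests assert to 1e-10. Identity-link
   predictions outside [0,1] trigger a warning with the out-of-range count;
   they are not clamped, as clamping would silently break the closed-form
   identity.
6. **Confidence intervals.** Default: 10,000 coefficient vectors drawn from
   a multivariate normal at the estimates with the robust covariance; the
   ACE is recomputed per draw and the 2.5th/97.5th percentiles reported.
   For identity-link (linear) functionals the per-draw ACE is computed
   through the exact linear map rather than row-wise prediction — the same
   distribution, much cheaper. A delta-method interval with an analytic
   gradient is the alternative; the method used is recorded on every
   estimate.

## Balance diagnostics

SMDs across exposure groups (tertiles by default): pooled-variance form for
binary variables, $|p_1-p_2| / \sqrt{(p_1(1-p_1)+p_2(1-p_2))/2}$; the
Mahalanobis-type multivariate form $\sqrt{d^\top S^{-1} d}$ on the first
$K-1$ level proportions with $S$ the average multinomial covariance for
multi-level categoricals (this reduces algebraically to the binary form at
two levels); $|m_1-m_2|/\sqrt{(s_1^2+s_2^2)/2}$ for continuous variables.
With three or more groups the reported SMD is the mean over all unordered
pairs, and group denominators are sums of non-missing category counts.
These conventions reproduce the printed SMDs of the motivating study's
baseline table to all three printed decimals (sex 0.115, age 0.249, smoking
0.124, diabetes 0.063), which is how they were selected; the weighted
variant replaces proportions/means/variances with weighted ones, treating
weights as normalized replication counts.

## Outcome coding

- Clinical dementia rating: any score above 0 is impairment.
- Subjective cognitive decline: case if ≥ 3 yes answers, or yes to the
  special item, or yes to any (default; "all" configurable) of the
  configured item clause. Participants missing a required item are flagged
  missing, never coded as non-cases.
- Continuous test scores: dichotomized at the 75th percentile of observed
  scores by default (type-7 / linear-interpolation quantile, matching R's
  default), or at fixed instrument cutoffs (36 verbal fluency, 48 memory,
  40 DO40, 24 Stroop, 11 CERAD praxis). Impairment is strictly below the
  threshold; ties at the threshold are healthy. The realized threshold is
  returned with every coding for audit.

## Synthetic cohorts

The generator emulates the structure such an analysis assumes, not any real
cohort's joint distribution:

- **Covariates**: 12 categorical baseline covariates drawn independently
  from configurable margins. The `table1_like` scenario uses margins pooled
  from the motivating study's printed baseline counts (e.g. age groups
  0.610 / 0.220 / 0.170); other scenarios use rounded versions of the same.
  Joint covariate dependence is deliberately not modelled.
- **Intakes**: gamma-distributed per food group with log-link
  covariate-dependent means — nonnegative and right-skewed like FFQ-derived
  g/d data. Shapes and base means (dairy 300 g/d shape 6, vegetables and
  fruits 200 shape 5, fish 40 shape 3, meat 100 shape 4, eggs 25, grains
  200, alcohol 50, sugary processed 80, high-fat 50) are free choices set
  once to plausible magnitudes; the study data report no intake variances
  or covariate-intake correlations to match. Total dairy is split into item
  columns by per-row Dirichlet shares so the aggregation stage is exercised
  end to end.
- **Outcome**: identity-link (linear probability) structural model by
  default — intercept 0.22, +0.02 per 100 g/d dairy, −0.01 per 100 g/d fish
  in the confounded scenario, plus covariate terms — so true ACEs are exact
  closed forms. A logit-link scenario provides the nonlinear case, with the
  true ACE evaluated directly from the structural model (validated against
  a brute-force potential-outcome simulation). Identity-link truths are
  validated at construction: the linear predictor is bounded over the
  1−1e-8 quantile of each food's intake distribution at its worst covariate
  pattern (taking extremes per covariate, since levels are mutually
  exclusive), and every generated row is re-checked — models that could
  leave [0,1] are rejected rather than clamped or re-drawn.
- **Censoring**: logistic in baseline covariates only (missing at random),
  ~20% dropout in the confounded scenario, heavier among older, diabetic,
  male and currently smoking participants; a ~1% death indicator overrides
  follow-up. Outcomes are missing exactly for non-followed rows.
- **Determinism**: one integer seed drives a single generator; identical
  truths produce bit-identical tables.

A deliberate design point: the estimator weights for *one* exposure, so
co-exposure coefficients in the all-component model are only deconfounded
if co-exposures do not share outcome-relevant confounders. In the
confounded scenario fish intake therefore varies with physical activity and
income — covariates outside the outcome model. If a co-exposure shares
confounders with the outcome, its coefficient (and hence substitution
effects involving it) inherits that confounding; this is a property of
single-exposure weighting itself, and users targeting substitution effects
should include the substituted food's confounders in the weight model's
adjustment set.

## Numerical and design choices

- Quantile conventions: type-7 for outcome dichotomization; lower order
  statistic for weight-truncation caps (see above). Both fixed and
  documented because membership of the clipped set depends on them.
- Tertile grouping for balance uses pandas `qcut`; descriptive
  servings-per-day strata are user-supplied cutpoints, never hard-coded,
  since a grams-per-serving convention would otherwise be invented.
- Butter is mapped full-fat non-fermented dairy; flavored yogurt is both
  fermented and sugary (sugary is an independent flag). The map ships as
  editable YAML.
- Eligibility bounds are strict inequalities (age > 59, MMSE > 23, kcal
  strictly inside the sex-specific bounds); exclusion reasons follow the
  fixed precedence age → MMSE → kcal → follow-up so logs are reproducible.
- The default analysis adjusts for nothing inside the outcome model beyond
  the food groups; an optional covariate list exists for exploration.
- No multiplicity adjustment is applied to the effect grids.

## Verification scale and what passing shows

The simulation checks run at 200 replicates of n = 5000 (recovery,
calibration, type-I error) and single cohorts of n = 10,000 (balance
restoration), sizes at which Monte-Carlo error is small relative to the
asserted tolerances: mean |bias| of addition and substitution ACEs below
0.005 against truths of +0.02/+0.03, CI coverage within [0.90, 0.98],
null rejection rate within [0.02, 0.08], and stabilized-weight means within
[0.95, 1.05] in ≥ 95% of replicates. Because the generator draws covariates
independently and uses Gaussian-compatible intake models, passing these
tests shows the estimator is correctly implemented and behaves as theory
predicts *under correct specification*; it does not show robustness to the
misspecifications real FFQ data bring (non-Gaussian conditional exposure
densities, measurement error, exposure-dependent dropout, joint covariate
structure). Those caveats apply equally to the method itself.

## Known limitations

- The Gaussian density-ratio weight model is linear and homoscedastic; with
  strongly skewed conditional exposure distributions the weights are
  misspecified (no nonparametric density-ratio option is provided, by
  scope).
- Substitution effects are coefficient differences within one fit
  (a leave-one-out refit mode exists for comparison); they assume the rest
  of the diet is held fixed under the swap.
- The repeated-measures mixed-model sensitivity analysis and
  competing-risk-of-death estimators are out of scope.
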