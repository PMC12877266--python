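# dietmsm

Marginal structural models (MSMs) for estimating the causal effect of dietary
exposures on binary health outcomes, built for the food *addition* and
*substitution* questions of nutritional epidemiology: *what happens to the
risk of an outcome if people add 100 g/d of a food to their diet, or replace
100 g/d of one food with another?*

The package implements the full estimation pipeline used in cohort analyses
of this kind — here motivated by dairy intake and cognitive impairment in
older adults — together with a synthetic-cohort generator with known causal
structure, so every stage can be validated against ground truth without
access to restricted cohort data.

## What it computes

For a continuous exposure $A$ (g/d), confounders $L$, follow-up indicator
$C$ and binary outcome $Y$:

1. **Stabilized inverse-probability-of-treatment weights** for the
   continuous exposure, using the Gaussian density-ratio construction
   $SW^A_i = \hat f(A_i) / \hat f(A_i \mid L_i)$, with the numerator a normal
   density at the marginal mean/SD of $A$ and the denominator a normal
   density centred at a linear-model prediction with the model's residual SD.
2. **Stabilized censoring weights** $SW^C_i = \hat P(C=1) / \hat P(C=1 \mid L_i)$
   from a logistic model, correcting missing-at-random loss to follow-up.
3. **Truncation** of each weight and of their product at a percentile cap
   (default 99.5th), trading a little bias for variance under near-positivity
   violations.
4. A **weighted binomial MSM** of the outcome on the exposure plus all other
   food groups composing the diet (the *all-component* model), so each
   coefficient holds the rest of the diet fixed.
5. **Average causal effects by marginal standardization**: the addition
   effect is the weighted mean of $\hat p(A_i + \Delta, \text{diet}_i) -
   \hat p(A_i, \text{diet}_i)$ over the analysis sample ($\Delta$ = 100 g/d
   by default); the substitution effect is the difference of two addition
   effects from the same fit. Parametric 95% CIs come from multivariate-normal
   simulation of the coefficients with the robust covariance (delta-method
   alternative included).
6. **Balance diagnostics**: standardized mean differences (SMDs) across
   exposure groups before and after weighting — pooled binary form,
   Mahalanobis-type (Yang–Dalton) form for multi-level categoricals,
   averaged over group pairs for 3+ groups — with the conventional < 0.1
   balance rule.

Supporting modules handle FFQ item-to-food-group aggregation with dairy
subtypes (fermented / non-fermented, full-fat / low-fat, sugary), cohort
eligibility screening with an auditable exclusion log, binary coding of
cognitive outcomes (clinical dementia rating, subjective cognitive decline,
percentile-dichotomized test scores), and a synthetic-cohort generator whose
known structural coefficients give exact or Monte-Carlo true effects.

## Worked example

```python
import dietmsm as dm

# a confounded cohort with known truth: +0.02 risk per 100 g/d dairy,
# -0.01 per 100 g/d fish, ~20% covariate-dependent dropout
truth = dm.generate_truth("confounded_positive", n=5000, seed=2)
cohort = dm.generate_cohort(truth)
print("true ACE:", dm.true_ace(truth, cohort, delta=100.0))

run = dm.run_full_analysis(cohort, dm.RunConfig(family="gaussian", seed=2))
report = run.balance_reports["total_dairy"]
print("max SMD before weighting:", round(report.max_smd_pre, 3))
print("max SMD after weighting:", round(report.max_smd_post, 3))
print(run.effects[["estimand", "substitution_food", "ace_pct",
                   "ci_low_pct", "ci_high_pct", "n"]].round(2).to_string(index=False))
```

prints

```
true ACE: 0.02
max SMD before weighting: 0.415
max SMD after weighting: 0.078
    estimand substitution_food  ace_pct  ci_low_pct  ci_high_pct    n
    addition                       1.64        0.40         2.89 4057
substitution              meat     1.36       -2.25         5.01 4057
substitution              fish     1.46       -4.48         7.48 4057
substitution              eggs    -6.15      -16.05         3.88 4057
substitution        vegetables     1.87       -0.01         3.76 4057
substitution            fruits     1.43       -0.67         3.55 4057
```

Reading the output: the covariates are strongly imbalanced across dairy
tertiles before weighting (max SMD 0.415) and balanced after (0.078 < 0.1).
The estimated addition effect, 1.64% (95% CI 0.40–2.89%), is this
replicate's estimate of the true +2% risk difference per added 100 g/d of
dairy; substitution rows estimate the risk difference of replacing 100 g/d
of the named food with dairy (positive = risk increases). Across 200 such
replicates the estimator recovers the truth with |mean bias| below 0.005
and ~95% CI coverage (see the test suite).

A command-line interface wraps the same stages:

```bash
dietmsm simulate --scenario confounded_positive --n 5000 --seed 2 --outdir sim/
dietmsm run sim/cohort.csv --outdir results/
dietmsm report results/
```

## Layout

- `src/dietmsm/cohort.py` — synthetic cohorts with known causal structure
- `src/dietmsm/exposures.py` — food-group aggregation, eligibility, cumulative-average exposures
- `src/dietmsm/outcomes.py` — binary outcome coding
- `src/dietmsm/weights.py` — stabilized IPW engine (treatment + censoring)
- `src/dietmsm/balance.py` — SMD balance diagnostics
- `src/dietmsm/msm.py` — weighted MSM, ACE functionals, parametric CIs
- `src/dietmsm/pipeline.py`, `src/dietmsm/cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
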