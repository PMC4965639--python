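# Methods

## Models

**Logistic regression.** `P(Y=1|x) = logit⁻¹(β₀ + Σᵢ βᵢxᵢ)`, fitted by
iteratively reweighted least squares (IRLS) to the maximum-likelihood
estimates.  Convergence is declared when the largest coefficient update
falls below 1e-8, with a cap of 100 iterations.  Each IRLS step solves the
weighted least-squares subproblem by QR-based `lstsq` on `√W·X` (numerically
stabler than forming `XᵀWX` directly); weights are floored at 1e-10 so the
step stays defined as fitted probabilities saturate.  Standard errors come
from the inverse observed information at the final estimate; Wald p-values
from the normal approximation.  Under complete or quasi-complete separation
the likelihood has no finite maximizer: the fit stops at the iteration cap,
sets `converged=False`, warns, and still returns finite coefficients and
probabilities — small subsamples (n = 50) do separate occasionally, and the
experiment harness must survive that.  Probability clipping is *not* applied;
the Q index's own undefined rule handles boundary probabilities.

**Linear discriminant analysis.** Two-group LDA in closed form: group means
μ₀, μ₁; pooled within-group covariance `S = (Σ_c Σ_{i∈c} (xᵢ−μ_c)(xᵢ−μ_c)ᵀ)/(n−2)`
(the unbiased two-group denominator); priors πᵢ equal to the empirical class
proportions by default (an `equal_priors` flag forces ½/½ — standard
discriminant practice on observational cohorts is proportional priors, so
that is the default).  Classification scores `Zᵢ = aᵢ + wᵢᵀx` with
`wᵢ = S⁻¹μᵢ`, `aᵢ = −½μᵢᵀS⁻¹μᵢ + log πᵢ`; cases go to the highest score.
The group-1 posterior under the same shared-covariance Gaussian model is
exactly `logit⁻¹(Z₁ − Z₀)`, which is what the B and Q indices consume.  A
pooled covariance with condition number above 1e12 is treated as singular
and reported with the offending predictor set.

**Shared conventions.** Binary predictors enter both models as their 0/1
codes treated as continuous inputs; k-level categoricals as k−1 dummies with
the first level as reference (so the design never collides).  Ties — a
probability of exactly 0.5, or equal classification scores — are assigned to
group 1, a fixed documented rule that keeps CE deterministic.

## Indices

- `CE = (# label mismatches)/n`, stored as a proportion; table renderers
  print it as a percentage.
- `B = 1 − (1/n) Σ (yᵢ − pᵢ)²`: 1 for perfect prediction, 0.75 for constant
  p = ½ on two equally sized groups.
- `Q = 1 + (1/n) Σ [yᵢ log₂ pᵢ + (1−yᵢ) log₂(1−pᵢ)]`: 1 perfect, 0 for
  constant p = ½, negative when worse than random.

Q's undefined rule has two readings, both implemented.  The **strict** rule
(default) declares Q undefined whenever any pᵢ ∈ {0, 1}, even if the
offending log term is multiplied by zero; under it a perfect prediction is
undefined rather than 1.  The **lenient** mode applies the `0·log 0 = 0`
convention, so only a certainly-wrong prediction (probability 0 assigned to
the true class, a genuine −∞) is undefined, and a perfect prediction scores
Q = 1.  The undefined marker is Python `None`; it propagates into rendered
tables as `NA(q-undefined)` and is never imputed.

## Experiment design

Predictor selection runs once, on the full base cohort: the full logistic
fit's Wald tests retain every predictor with p < α (default 0.05; for a
categorical, any of its dummies suffices).  The selected set is reused in
every subsample so that sample-size effects are not confounded with
selection noise.  For each of two series and each size in
(50, 100, 150, 200, 220) one simple random subsample without replacement is
drawn (redrawn up to 100 times if a class is missing), both models are
fitted on it, and all three indices are computed by **resubstitution** —
fit and evaluate on the same subsample.  Resubstitution is the design's
evaluation rule because one index triple is reported per subsample with no
hold-out, and it makes the total-sample rows (the full base cohort)
identical across series.  An optional `replicates` setting averages each
cell over R independent subsamples; it is off (R = 1) by default to mirror
the two-series design.

Subsample index sets are derived from `(seed, series, size-position,
replicate)` only — never from the cohort's values — so the categorized
variant run with the same seed draws exactly the same subjects and the two
tables are paired row-for-row.  Within-series subsamples are independent
draws, not nested; nesting across sizes would be an equally defensible
reading, but independence is the simplest reproducible one.

The categorized variant cuts duration at its empirical tertiles by default
(configurable cutpoints; left-closed/right-open intervals).  Cutpoints that
collapse duration to a single observed level drop the predictor with a
warning instead of failing.  Per-cell model failures (separation, singular
covariance after categorization) are recorded as `NA(reason)` cells, never
aborting the table.

## Synthetic cohort generator

The generator emulates the motivating study population: n = 243, binary
depression outcome, and the three retained predictors — satisfaction
(binary), family history of depression (binary), duration of cancer in
years (continuous, positive).

**logistic regime (default preset).** satisfaction ~ Bernoulli(0.5), family
history ~ Bernoulli(0.25), duration ~ lognormal(μ = 1.0, σ = 0.6) (median
≈ 2.7 years, right-skewed, as disease durations are); outcome ~
Bernoulli(logit⁻¹(−0.6 − 1.3·satisfaction + 1.5·family_history +
0.18·duration)).  These coefficients were calibrated once, by Monte-Carlo
integration of the link over the covariate marginals (2×10⁶ draws), to put
the outcome prevalence at 0.436 and the Bayes misclassification rate at
0.321 — matching the study's reported total-sample error near one third.
Sign conventions are clinical: satisfaction protects, family history and
longer duration increase risk.

**lda_gaussian regime.** Class first (prevalence 0.4), then duration ~
N(2.8, 2.0) in class 0 and N(3.6, 2.0) in class 1 (shared variance — LDA's
homogeneity assumption holds), and per-class Bernoulli binaries
(satisfaction 0.55/0.40, family history 0.20/0.32).  The binary effects are
deliberately mild: for success probabilities near ½ the Bernoulli log-odds
ratio and the LDA weight `Δp/(p̄(1−p̄))` nearly coincide, so the class
log-posterior stays essentially linear and the asymptotic LR/LDA agreement
this regime exists to demonstrate actually holds.

What the generator does **not** emulate: the remaining nine questionnaire
variables of the original study (sex, marital status, education, …), any
missing-data mechanism (the study analysed complete cases), measurement
error, or covariate correlation within a class beyond the shared Gaussian
block.  Passing tests therefore show that the pipeline's statistics behave
as theory predicts on data satisfying (or cleanly violating) each model's
assumptions — not that these two models would tie or differ by any
particular margin on the real, unpublished cohort, whose table values are
not reproducible from synthetic data.

## Numerical and test-scale choices

- IRLS: tolerance 1e-8 on the max coefficient update, 100 iterations,
  weight floor 1e-10; log-likelihood is computed via `logaddexp` and is
  non-decreasing along the path (a tested invariant).
- LDA: singularity threshold at condition number 1e12.
- All randomness flows from integer seeds through `numpy.random.Generator`;
  identical configuration implies bit-identical cohorts, subsamples and
  tables.
- Simulation sizes in the test suite: parameter recovery uses n = 50,000
  cohorts over 20 seeds; asymptotic LR/LDA agreement n = 20,000; the
  type-I-error check of the Wald screen runs 200 replicates of n = 2,000
  (the null rejection rate is size-free at these n, so the smaller
  per-replicate cohort keeps the suite fast at identical power of the
  check); the SRSWOR inclusion-frequency check uses 2,000 draws.  These
  sizes are the package's own accuracy/runtime trade-off.

## Known limitations

- Two outcome groups only; no quadratic discriminant, no regularized fits,
  no ROC/AUC machinery, no cross-validated or bootstrap-corrected error
  estimates — resubstitution is the design's rule and is optimistic in an
  absolute sense even though it compares the two models fairly.
- Under separation the reported LR "estimates" are the iteration-cap
  stopping point of a divergent path; they classify sensibly but their
  magnitudes are meaningless (flagged via `converged=False`).
- The Wald screen is a single-pass marginal test, not a search over model
  subsets; with correlated predictors it can drop jointly informative ones.
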