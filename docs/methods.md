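# Methods

This note documents the statistical models implemented in `stratmr`, the
choices made where several conventions were defensible, and what the
synthetic-data evaluation does and does not establish.

## Estimation model

All causal estimates are one-sample allelic-score MR ratio estimates.
Genetic associations are estimated by linear regression (exposure,
continuous negative control) and maximum-likelihood logistic regression
(binary outcomes), adjusted for a named covariate set:

| set | contents | used for |
|---|---|---|
| `linear_default` | age, sex, centre indicators, pc1–pc10 | whole-population analyses |
| `nonlinear_expanded` | `linear_default` + age², age·sex, age²·sex | stratum-specific analyses |
| `negative_control` | centre indicators, pc1–pc10 | age/sex control outcomes |

Age is mean-centred inside the quadratic and interaction terms purely for
numerical conditioning; the model space is unchanged. Centre enters as
one-hot indicators against a reference level.

The ratio estimate per 10 nmol/L is `10·β_GY/β_GX` with first-order
delta-method SE `10·se_GY/|β_GX|`. The term from uncertainty in β_GX is
omitted by default because the instrument is strong in every setting in
scope (partial F in the hundreds to thousands, making that term of relative
order 1/F); `second_order=True` restores it. Confidence intervals and
p-values use the normal reference — sample sizes here are 10³–10⁵ per
stratum, where the t/normal distinction is irrelevant. If |β_GX| < 2·se_GX
the code refuses to form a ratio (`WeakInstrumentError`) rather than return
a numerically explosive estimate.

Rare outcomes inside small strata can separate; a Jeffreys-prior
(Firth-style) penalized logistic fallback is implemented behind
`firth=True`, default off so that headline behaviour is standard ML.

## Instrument construction

Variants are selected per gene region by forward stepwise regression of the
exposure on candidates plus the analysis covariates: at each step the
candidate with the smallest conditional p-value enters if it is below
`p_enter` (default 1e-6, a conditional genome-wide-style stringency;
configurable). Selection is forward-only — the simplest procedure
consistent with a "stepwise selection" description — and candidates are
scanned lexicographically so p-value ties resolve deterministically.
Weights are the conditional coefficients of the final joint model, so
moderately correlated variants are admitted when each predicts independent
exposure variation; perfectly collinear candidates are skipped with a
warning.

Instrument strength is reported as the incremental R² of the score over the
covariate-only model together with the **1-df score-based partial F**,
`(n−p−1)·r²_partial/(1−r²_partial)`. Note that published cohort analyses
sometimes quote an F statistic computed on a different convention (e.g. a
multi-variant F with one degree of freedom per variant); the 1-df score
convention used here is the one that matches the single-instrument ratio
estimator, and the two are not numerically interchangeable.

## Stratification

**Doubly-ranked (primary).** Sort by score; chunk into pre-strata of
`pre_stratum_size` (default 50) consecutive individuals; within a
pre-stratum of size m the individual at exposure rank r joins stratum
⌈rS/m⌉. With P divisible by S every pre-stratum contributes exactly P/S
members to each stratum. Conventions the method's description leaves open:

- *Remainder handling*: a final pre-stratum of size m < P is allocated by
  the same ⌈rS/m⌉ rule, so no one is dropped when n is not divisible by P.
- *Score ties*: broken by adding a seeded uniform perturbation strictly
  smaller than the smallest nonzero score gap — deterministic given the
  seed, and order-preserving for distinct scores.
- Stratification uses the **season-adjusted** exposure, the same variable
  the estimates are scaled on.

**Residual (secondary).** S-quantile groups of the residual of the
(optionally log-transformed) exposure after regressing on score and
covariates. Valid only when the genetic effect on the exposure is constant;
with the generator's `effect_heterogeneity = 0` the two methods agree for
>80% of individuals, and this agreement is a test in the suite.

**Bootstrap averaging.** Each replicate removes `n_remove` participants
(default 12) uniformly without replacement from its own seeded substream,
re-stratifies and re-estimates; per-stratum log-ORs are combined with
Rubin's rules (mean; within-variance + (1+1/B)·between-variance). Choices:
combination is on the log-OR scale (additivity/normality; ORs are
exponentiated afterwards); the reference distribution is normal with no
small-sample df adjustment (B = 100 replicates of near-identical data sets,
between-variance a small fraction of total); strata are matched across
replicates by index, which is stable because stratum identity is defined by
exposure rank and only ~0.01% of individuals change per replicate. A
replicate whose stratum fails (e.g. single-class outcome) is recorded as
missing for that stratum and the combination reports the replicate count
used. With `n_remove = 0` the procedure is exactly idempotent with
single-run estimation.

## Negative controls and multiplicity

Per doubly-ranked stratum, the score's association with age (linear, years)
and sex (logistic, log-OR) is scaled by 10/β_GX of the same stratum.
Because the generator draws age and sex independently of genotype, the
expected result is null by construction; the generator's optional
participation model (probability depending on a score-by-sex interaction)
induces exactly the kind of within-stratum sex association that flags
selection bias, and the suite verifies both directions. Sex estimates are
reported on the log-OR scale (null 0). Multiplicity thresholds are plain
Bonferroni, α/n_outcomes/n_strata, returned at full precision.

## Power

For a binary outcome with case fraction K, instrument R² = r², exposure SD
sd and odds ratio OR per 10 nmol/L, the analytic power of the two-sided
α-level MR test in the direction of the effect is
Φ(|ln OR·sd/10|·√(n·r²·K(1−K)) − z_{1−α/2}); at OR = 1 this limits to α/2.
The approximation ignores logistic non-collapsibility, which is small for
rare outcomes: the suite's simulation oracle (simulate → estimate → count
directional rejections, 16,000 replicates at n = 10,000) agrees within 0.01
across OR 0.85–1.3, inside the 0.02 tolerance asserted.

## Synthetic cohort generator

The generator emulates the joint structure the analyses assume — not any
real data set:

- **Genotypes.** Two independent Bernoulli haplotypes per variant
  (Hardy–Weinberg marginals) from a latent Gaussian threshold model. The
  latent correlation is obtained by root-finding on the bivariate-normal
  orthant probability so the realized *dosage* correlation equals the
  target `ld_r` (a naive latent correlation would attenuate after
  thresholding). Pairwise targets beyond the Fréchet bound for unequal
  frequencies are capped at 95% of the bound, mirroring the real constraint
  on LD between variants of disparate frequency.
- **Exposure.** X = μ + s·(G−E[G]) + A·cos(2π(month−7)/12) + ε. The
  per-individual multiplier s is lognormal with mean 1 and coefficient of
  variation `effect_heterogeneity` — a one-parameter control of the
  non-constant genetic effect that motivates the doubly-ranked method.
  Weights are rescaled once so var(G) = r²·sd², and the noise variance is
  solved so the season-adjusted exposure has SD exactly `exposure_sd`; the
  calibration targets therefore refer to the analysis variable. Months are
  uniform; the seasonal peak is placed in July, which puts October at phase
  zero so the adjusted and raw means coincide.
- **Outcomes.** Bernoulli draws from logistic models with f(X) = 0 (null),
  β·X/10 (linear) or β·min(X−threshold, 0)/10 (threshold: risk responds to
  the exposure only in the deficient range). The intercept is root-found on
  the sample so the mean risk hits the target prevalence to 1e-10.
- **Covariates / negative controls.** Age ~ N(57.1, 8.1) truncated to
  [40, 70], sex Bernoulli(0.534), uniform centres, standard-normal PCs —
  all independent of genotype.
- **Selection (optional).** Participation probability
  expit(logit(base) + a·z_G + b·sex + c·z_G·(2·sex−1)); a nonzero c creates
  the in-sample score–sex dependence used to demonstrate the
  negative-control diagnostic.
- **Randomness.** Everything flows from one integer seed through named
  `SeedSequence` substreams (genotypes, months, heterogeneity, noise,
  covariates, per-outcome, selection, tie-breaks, bootstrap), so any stage
  is reproducible in isolation.

Default conditions: n = 100,000; 21 variants in four regions with
within-region dosage correlation 0.3; exposure 55.4 ± 19.3 nmol/L with
score R² target 4.7%; seasonal amplitude 10 nmol/L (a realistic
mid-latitude swing; only the existence of a seasonal shift is essential);
`effect_heterogeneity` 0.2 (moderately non-constant genetic effect, the
regime the doubly-ranked method targets); 22 centres; outcome prevalences
0.7/2.0/1.3/3.9%. Exposure is floored at 0.5 nmol/L (a detection-limit
analogue preserving positivity; <0.3% of draws affected, shifting the mean
by ~0.01 nmol/L).

## Problem sizes in the test suite and acceptance script

The statistical checks run at sizes chosen to make their Monte-Carlo error
small relative to the asserted tolerances: type-I error over 1,000 cohorts
of n = 10,000; parameter recovery and calibration at n = 100,000;
threshold-pattern detection over 12 seeds at n = 200,000; the power oracle
with 16,000 replicates per grid point at n = 10,000. The acceptance script
uses n = 100,000 cohorts with the full B = 100, m = 12 bootstrap.

## What passing tests show — and what they do not

The generator reproduces the *statistical* structure of a large volunteer
cohort (calibrated moments, LD, rare outcomes, seasonality, non-constant
genetic effects, optional selection). It does not emulate real-data
features such as population stratification confounding, genotyping or
phenotype misclassification error, relatedness, missing data, or genuine
pleiotropy of the instrument variants. Passing tests therefore establish
that the estimators are correct and well-calibrated under the assumed
model, not that those assumptions hold in any particular cohort. Known
limitations: the delta-method SE understates uncertainty for genuinely weak
instruments (guarded by the 2-SE refusal rather than fixed); residual-method
strata are biased when the genetic effect is heterogeneous (by design —
that is the contrast the package exists to exhibit); no
continuous dose–response (fractional polynomial) estimation is provided,
only stratum estimates; and no summary-statistic (two-sample) MR or
pleiotropy-robust estimators are included, the design being one-sample
allelic-score MR throughout.
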