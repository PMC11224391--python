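# stratmr

Linear and non-linear **one-sample Mendelian randomization (MR)** with
allelic-score instruments, for continuous exposures and rare binary
outcomes. The package was built around the question of whether circulating
25-hydroxyvitamin D [25(OH)D] causally affects chronic pain and depression:
whole-population analyses answer "would shifting everyone's vitamin D level
help?", while exposure-stratified (non-linear) analyses answer "does an
effect exist specifically in the deficient part of the population?" — the
pattern expected under a threshold mechanism. It is aimed at
biostatisticians and genetic epidemiologists who want the full pipeline —
instrument construction, estimation, stratification, diagnostics and power —
as tested, composable library code, plus a synthetic cohort generator that
reproduces the statistical structure such analyses assume.

## The methods

**Ratio (Wald) estimate.** With an allelic score
G = Σ_v w_v · dosage_v as the instrument, the causal log odds ratio per
10 nmol/L of genetically-predicted exposure is

```
β̂ = 10 · β̂_GY / β̂_GX ,    se(β̂) = 10 · se(β̂_GY) / |β̂_GX|
```

where β̂_GY is the covariate-adjusted logistic coefficient of the score on
the outcome and β̂_GX the linear coefficient on the exposure (first-order
delta method; a second-order option exists).

**Doubly-ranked stratification.** Stratifying directly on the exposure
would induce collider bias, because the exposure is downstream of the
instrument. Instead, individuals are ranked by the score into pre-strata of
50, then ranked by exposure *within* each pre-stratum; with S strata the
individual with within-rank r (of m) joins stratum ⌈rS/m⌉, so each
pre-stratum of 50 sends exactly ten people to each of five strata. The
resulting strata differ strongly in exposure but are approximately balanced
in the instrument, making stratum-specific ratio estimates valid even when
the genetic effect on the exposure is not constant across the population.
A residual-method stratifier (quantiles of exposure minus its regression on
the score; identity or log scale) is included as the secondary approach.

**Bootstrap averaging with Rubin's rules.** Stratum estimates are
stabilized by removing 12 participants at random, re-stratifying and
re-estimating, 100 times; replicate log-ORs are combined as
point = mean, total variance = mean within-replicate variance +
(1 + 1/B) · between-replicate variance.

**Diagnostics and design.** Age and sex — which the exposure cannot
cause — serve as negative-control outcomes per stratum (adjusted for centre
and principal components only). Multiplicity uses α / n_outcomes /
n_strata. An analytic power calculator for the binary-outcome MR test,
power = Φ(|ln OR · sd_X/10| · √(n·r²·K(1−K)) − z_{1−α/2}), is validated
against a simulation oracle in the test suite.

**Synthetic cohorts.** The generator draws 21 variants in four vitamin-D
gene regions (*GC*, *DHCR7*, *CYP2R1*, *CYP24A1*) with within-region LD,
builds the exposure from the weighted score (optionally with a lognormal
per-individual effect multiplier — the non-constant-effect regime), adds a
sinusoidal seasonal term removed again by mean-shifting to October, and
draws rare outcomes from logistic models with null, linear or threshold
causal shapes. Defaults: exposure 55.4 ± 19.3 nmol/L, score R² = 4.7%,
prevalences 0.7/2.0/1.3/3.9%.

## Worked example

A cohort of 100,000 with a protective effect confined to 25(OH)D below
25 nmol/L (log-OR −0.3 per 10 nmol/L below the threshold, depression-like
prevalence 3.9%):

```python
from stratmr import (CohortSimulator, EffectSpec, GeneratorConfig, NonlinearMR,
                     build_score, instrument_strength, run_linear_analysis)

eff = EffectSpec(name="depression", shape="threshold", beta=-0.3,
                 threshold=25.0, target_prevalence=0.039)
sim = CohortSimulator(GeneratorConfig(n=100_000, effects=(eff,)))
cohort = sim.generate(seed=1)
spec = sim.score_spec()

strength = instrument_strength(build_score(cohort, spec).to_numpy(),
                               cohort["exposure_adj"].to_numpy())
print(f"instrument R^2 = {strength.r2:.4f}, F = {strength.f_stat:.0f}")

print(run_linear_analysis(cohort, spec, ["depression"]))

nl = NonlinearMR(score_spec=spec, outcomes=["depression"], n_strata=5,
                 n_reps=100, n_remove=12, random_state=1).fit(cohort)
print(nl.results_)
```

Output (abridged):

```
instrument R^2 = 0.0475, F = 4991
   outcome    or  ci_low  ci_high     p
depression 0.979   0.907    1.057 0.591
 stratum  mean_exposure    or  ci_low  ci_high     p
       1         29.578 0.860   0.723    1.022 0.087
       2         45.413 1.043   0.871    1.251 0.646
       3         55.338 1.009   0.849    1.198 0.922
       4         65.274 1.023   0.863    1.214 0.790
       5         81.200 0.986   0.829    1.173 0.875
```

The whole-population estimate is null (OR 0.98): averaged over everyone,
shifting vitamin D does little. The stratified analysis localizes the
protective signal to the lowest-exposure quintile (OR 0.86, stratum mean
29.6 nmol/L) while the other four strata sit on the null — exactly the
signature of a threshold effect, visible only where deficient individuals
are concentrated.

The same pipeline is scriptable from the shell:

```bash
stratmr simulate --out run/ --seed 1
stratmr nonlinear --cohort run/cohort.tsv --score-spec run/spec.tsv \
    --outcomes depression --strata 5 --seed 1 --out run/nonlinear.csv
stratmr run --config examples/run.yaml        # full pipeline + manifest
```

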