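# Full-pipeline run on a generated cohort (small sizes so it finishes in
# about a minute; raise n / bootstrap_reps for production-scale runs).
seed: 1
output_dir: run_out
analyses: [linear, nonlinear_5, nonlinear_3, negative_controls, power]
score_source: generator
bootstrap_reps: 10
bootstrap_remove: 12
generator:
  n: 20000
  n_centres: 10
  exposure_mean: 55.4
  exposure_sd: 19.3
  score_r2_target: 0.047
  effect_heterogeneity: 0.2
  seasonal_amplitude: 10.0
  effects:
    - name: depression
      shape: threshold
      beta: -0.3
      threshold: 25.0
      target_prevalence: 0.039
    - name: clinical_fatigue
      shape: null
      target_prevalence: 0.020
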