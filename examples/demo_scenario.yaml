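# Paired demonstration scenario: both drugs on the same 200 virtual patients
# sampled with the retrospective-cohort characteristics.
#   tkisim run examples/demo_scenario.yaml --out results/demo
scenario: demo-paired
master_seed: 2024
output_dir: results/demo
population:
  spec: li_cohort
  n_patients: 200
trial:
  drugs: [osimertinib, gefitinib]
  horizon_months: 24.0
  assessment_interval_weeks: 6.0
stats:
  n_bootstrap: 500
  subsample_fraction: 0.1
  alpha: 0.05
  similarity_threshold: 0.80
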