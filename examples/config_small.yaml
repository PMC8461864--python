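# Desk-scale pipeline configuration: simulate a small world, then run
# every stage.  Thresholds are lowered from the production defaults
# (1000 patients per drug / 1000 case samples per disease) to match the
# simulated sample sizes.
seed: 1
out_dir: outputs/small
alpha: 0.05
lambda_strategy: cv          # or a fixed number, e.g. 2.5
min_patients_per_drug: 10
min_samples_per_disease: 50
k_grid: [5, 10]
group_size: 5
n_clusters: 2
simulate:
  ehr:
    n_patients: 150
    n_drugs: 20
    n_labs: 8
    measurements_per_patient: [6, 10]
    baseline_mean: 50.0
    baseline_sd: 10.0
    noise_sd: 1.0
    exposure_prob: 0.15
    effect_magnitude: 1.0
    effect_labs_per_drug: 3
  survey:
    n_cases: 400
    n_controls: 400
    n_diseases: 4
    shifted_labs_per_disease: 4
    shift_sd_units: 0.8
    lab_mean: 50.0
    lab_sd: 10.0
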