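# Default run configuration: synthetic TLE/NC cohort and analysis options.
cohort:
  patients:
    n: 18
    male_count: 10
    age_mean: 30.4
    age_sd: 8.16
    viq_mean: 90.00
    viq_sd: 11.57
    piq_mean: 95.06
    piq_sd: 10.90
  controls:
    n: 29
    male_count: 17
    age_mean: 27.8
    age_sd: 5.78
    viq_mean: 109.45
    viq_sd: 11.91
    piq_mean: 109.00
    piq_sd: 10.51
  duration_mean: 13.90
  duration_sd: 7.15
  onset_mean: 16.28
  onset_sd: 10.69
  duration_onset_r: -0.632
  min_age: 18.0
  # temporal/limbic regions carrying the planted patient effect
  affected_regions: [32, 35, 36, 39, 40, 41, 81, 83, 85, 87, 89]
  # high-degree template regions (hub targets)
  hub_regions: [4, 43, 51, 60, 67, 68, 73, 74, 85, 86, 90]
  # regions whose edge strength co-varies with performance / verbal IQ
  piq_regions: [2, 22, 54, 57, 66]
  viq_regions: [21]
  fa_attenuation: 0.85
  duration_slope: 0.012
  iq_coupling: 0.06
  edge_noise_sd: 0.02
  density_calibration: 0.797
  seed: 0
weight_to_length: reciprocal
n_null: 100
swaps_per_edge: 10
fa_threshold: 0.2
min_count: 1
sd_multiplier: 1.0
q_level: 0.05
seed: 0
compute_sigma: true
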