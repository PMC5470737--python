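n_individuals: 304112
divorced_fraction: 0.07877360972273373
study_months: 156
episode_model: stress_relief
episode_mu: -6.0
episode_sigma: 4.5
episode_curve: null
episode_probability: 0.06
persistence_lambda: 0.04
response_alpha: 1.0
background_rate: 0.02
trend_slope: 0.00015
drug_class_tags: null
seed: 20170614
window:
- -60.0
- 60.0
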