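# Default enclosure scenario: two subspecies bred in demes over ~9 months,
# with read depths spanning the observed sequencing range.
n_founders_per_subspecies: 12
n_demes: 3
p_within_deme_mating: 0.9
experiment_length: 270
litter_size_mean: 6.0
n_asv: 500
depth_range: [2374, 45661]
w_vertical: 1.0
w_social: 1.0
w_env: 1.0
sigma_individual: 0.4
age_profile:
  weaning_age: 23.0
  peak_age: 65.0
  decay_rate: 0.04
seed: 0
subspecies: [MMM, MMD]
max_individuals_per_subspecies: 100
gestation_days: 19
maturity_age_days: 40
litter_interval_days: 30
p_litter_per_cycle: 0.5
founder_age_at_release: 60
n_nestboxes_per_subspecies: 6
# The demic-contrast values below are illustrative: no quantitative
# social-preference estimates exist for MMD vs MMM, so the contrast is
# exercised by varying deme_preference / p_within_deme_mating per scenario.
deme_preference: 0.8
visits_per_mouse: 60
visit_duration_mean_s: 600.0
drop_fraction: 0.0
n_mixing_rounds: 3
env_log_sd: 1.5
ileum_keep_fraction: 0.05
ileum_background: 0.01
sections: [ileum, cecum, colon]
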