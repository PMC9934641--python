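# Minimal end-to-end smoke run: 3 subjects, 30 trials/category, reduced
# synthesis rate and 20 CV iterations. Finishes in well under two minutes
# on one CPU.

[session]
n_trials_per_category = 30
fs_raw_hz = 250.0
n_channels = 64

[signal]
amp_sensory = 18.0
noise_sd = 20.0
artifact_rate = 0.05

[cohort]
n_subjects = 3
seed = 11

[preprocess]
fs_target_hz = 125.0
min_trials = 0

[decode]
n_iterations = 20
group_size = 5

[stats]
n_permutations = 0
correction = "bonferroni"
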