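# Example cohort specification for `metsmarkov simulate --spec ...`.
# Omitted keys fall back to the defaults of metsmarkov.simulate.CohortSpec;
# `params` (the generating intensity set) defaults to the package's reference
# scenario, metsmarkov.params.example_parameters().
n_subjects: 5000
baseline_state_probs: [0.3555, 0.4733, 0.1712]   # FMD / MMD / MetS at entry
age_bands: [[20, 30], [30, 40], [40, 50], [50, 60], [60, 70], [70, 80]]
age_weights: [0.1005, 0.2482, 0.2841, 0.1792, 0.1250, 0.0630]
prop_female: 0.60
screen_schedule: annual        # or: irregular (1-4 year gaps, uniform)
followup_years: 3.0            # screens at t = 0, 1, 2, 3
attendance_prob: 1.0           # per-screen attendance after baseline
refresh_years: 1.0             # age refresh interval for intensities
seed: 20210211
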