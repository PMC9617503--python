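# Demo pipeline configuration: simulate a 24-participant two-season cohort
# and run every stage into out_dir.
out_dir: scratch/demo_run
seed: 7
n_participants: 24
seasons: [W1, S]
n_boot: 0
n_perm: 0
dlmo_threshold: 3.0
growth_scheme: seven_month
growth_months: 7.0
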