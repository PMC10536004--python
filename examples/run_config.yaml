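# Example configuration for `teacat run --config examples/run_config.yaml`.
# Omitted keys take their defaults; thresholds default to the study's
# identifiability criteria (ssr 1e-5, fsd 0.5, correlation 0.8).
n_subjects: 6
seed: 11
inter_subject_cv: 0.30
measurement_cv: 0.20
output_dir: scratch/demo_run
# init_overrides:
#   "small_intestine->liver": 0.25
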