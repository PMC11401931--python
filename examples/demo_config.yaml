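# Demo configuration: full 9-subject synthetic session with reduced
# permutation counts so `laminardyn run-all --config examples/demo_config.yaml`
# finishes in well under 15 minutes on one CPU.
#
# Every parameter the analysis leaves open surfaces here with its default:
#   hp_cutoff_s: 128      # high-pass cutoff (s); filter family is Butterworth-3
#   cost: 1.0             # SVM cost parameter
#   n_trs: 17             # TRs per trial epoch (32 s at TR = 2 s)
#   alpha: 0.05           # cluster-forming and cluster-level threshold

seed: 7
out: out-demo
contrast: load
n_subjects: 9
n_voxels_per_layer: 60
pattern_dynamics: dynamic

# reduced from the full 250 / 10,000 for demo speed
n_subject_perm: 50
n_population_draws: 2000
n_matrix_perm: 2000

noise_sigma: 1.0
ar1_rho: 0.3
drift_order: 3
drift_scale: 1.0
subject_amp_sd: 0.25
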