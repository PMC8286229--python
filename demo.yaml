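# Small end-to-end demo configuration (a couple of minutes on one CPU).
# Omitted keys fall back to the study defaults (100 nulls, 10,000
# permutations, 100/1000 Louvain runs, densities 0.10-0.25).
pipeline:
  densities: [0.10, 0.15, 0.20, 0.25]
  n_nulls: 20
  n_louvain_subject: 20
  n_louvain_null: 10
  n_louvain_group: 500
  n_perm: 2000
  fdr_q: 0.05
  seed: 1
simulate:
  module_sizes: [10, 10, 10, 10]
  module_labels: [fronto_parietal, default_mode, visual, somatomotor_hand]
  r_within: 0.5
  r_between: 0.1
  coupling_delta: 0.15
  n_weaker: 10
  n_stronger: 5
  delta_z: 0.4
  n_subjects: 21
  n_timepoints: 282
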