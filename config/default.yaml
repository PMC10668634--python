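# Default pipeline configuration (mirrors lungplast.pipeline.DEFAULT_CONFIG).
# Any subset of keys may be overridden; nested sections merge shallowly.
seed: 7
n_top: 100
ssgsea_weight: 0.75
n_permutations: 1000
nmf:
  rank: 3
  n_restarts: 20
oncogps:
  k_nodes: 9
  n_states: 4
  nmf_restarts: 5
kras_panel:
  n_cell_lines: 60
  module_size: 1000
  n_states: 3
gating:
  n_cells: 100000
  dualpos_fraction: 0.026
  notch_positive_fraction: 0.5035
qpcr:
  true_fold_changes:
    Rage: 4.0
    Aqp5: 2.0
    Sftpc: 1.5
  noise_sd: 0.0
engraftment:
  Rag1KO:
    dualpos: [7, 10]
    typeII: [2, 10]
  NOD_SCID:
    dualpos: [8, 9]
    typeII: [0, 8]
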