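# Default three-library study design for the synthetic repertoire generator.
#
# Pre-selection library sizes, canonical-class mixtures and CDR-length
# distributions emulate an immunized-sheep scFv phage-display experiment:
# three heavy+lambda libraries of 110+80, 77+30 and 196+95 pre-selection
# sequences, panned against small-molecule haptens to yield panels of 3-8
# unique post-selection clones. Mixture weights are the pre-selection
# canonical-combination and CDR-length frequencies the generator targets.
libraries:
  - library_id: lib1
    n_pre_heavy: 110
    n_pre_lambda: 80
    heavy_mixture: {"1-1": 0.973, "2-4": 0.010, "1-4": 0.010, "2-1": 0.007}
    lambda_mixture: {"6-1-X": 0.513, "2-1-5": 0.112, "6-1-5": 0.112,
                     "2-1-X": 0.100, "5-1-X": 0.080, "5-1-5": 0.053,
                     "5-1-4": 0.030}
    h3_lengths: {9: 0.025, 10: 0.20, 11: 0.15, 12: 0.10, 13: 0.118,
                 14: 0.145, 15: 0.12, 16: 0.092, 17: 0.05}
    l3_x_lengths: {10: 0.85, 12: 0.10, 13: 0.05}
    mutation_rate_fw: 0.01
    mutation_rate_cdr: 0.15
    panels:
      - {target: SQA, n_post_clones: 6, post_copies: 3}
      - {target: POR, n_post_clones: 3, post_copies: 3}
    planted_conserved:
      heavy: ["66", "67", "70", "71", "72", "74", "86", "87", "88"]
      lambda: ["57", "58", "59", "60", "61", "62", "64"]
    planted_mode: identical
  - library_id: lib2
    n_pre_heavy: 77
    n_pre_lambda: 30
    heavy_mixture: {"1-1": 0.948, "2-1": 0.026, "3-1": 0.013, "1-4": 0.013}
    lambda_mixture: {"6-1-X": 0.467, "6-1-5": 0.200, "5-1-X": 0.166,
                     "2-1-X": 0.100, "5-1-4": 0.067}
    h3_lengths: {9: 0.013, 10: 0.20, 11: 0.18, 12: 0.167, 13: 0.12,
                 14: 0.16, 15: 0.10, 16: 0.06}
    l3_x_lengths: {10: 0.85, 12: 0.10, 13: 0.05}
    mutation_rate_fw: 0.01
    mutation_rate_cdr: 0.15
    panels:
      - {target: COP, n_post_clones: 8, post_copies: 3}
    planted_conserved:
      heavy: ["66", "67", "70", "71", "72", "74", "86", "87", "88"]
      lambda: ["57", "58", "59", "60", "61", "62", "64"]
    planted_mode: identical
  - library_id: lib3
    n_pre_heavy: 196
    n_pre_lambda: 95
    heavy_mixture: {"1-1": 1.0}
    lambda_mixture: {"6-1-X": 0.453, "2-1-X": 0.177, "5-1-X": 0.147,
                     "6-1-5": 0.100, "2-1-5": 0.070, "5-1-5": 0.053}
    h3_lengths: {9: 0.086, 10: 0.15, 11: 0.15, 12: 0.074, 13: 0.16,
                 14: 0.15, 15: 0.13, 16: 0.10}
    l3_x_lengths: {10: 0.85, 12: 0.10, 13: 0.05}
    mutation_rate_fw: 0.01
    mutation_rate_cdr: 0.15
    panels:
      - {target: HSL, n_post_clones: 6, post_copies: 3}
    planted_conserved:
      heavy: ["66", "67", "70", "71", "72", "74", "86", "87", "88"]
      lambda: ["57", "58", "59", "60", "61", "62", "64"]
    planted_mode: identical
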