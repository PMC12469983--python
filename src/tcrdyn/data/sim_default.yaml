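# Full default simulator configuration: a 5-patient paired cohort with
# expanded-clone contraction after the intervention and four TRAV-TRBV
# pairing tilts (two enriched post, two enriched pre) at |log OR| = ln 8.
n_patients: 5
cells_per_sample: null        # null: per-patient uniform draw in [1500, 3500]
usage_concentration: 1.0
patient_noise: 0.01
expanded_fraction_pre: 0.08
expanded_size_range: [6, 100]
geometric_p: 0.5
contraction_factor: 0.3
persistence_prob: 0.6
pairing_effects:
  - {trav: TRAV12-2, trbv: TRBV14, log_odds: 2.0794415416798357, condition: post_GFD}
  - {trav: TRAV10, trbv: TRBV28, log_odds: 2.0794415416798357, condition: post_GFD}
  - {trav: TRAV2, trbv: TRBV6-2, log_odds: 2.0794415416798357, condition: pre_GFD}
  - {trav: TRAV26-2, trbv: TRBV7-2, log_odds: 2.0794415416798357, condition: pre_GFD}
cdr3_length_support: [8, 20]
cdr3_length_mode: 14
seed: 0
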