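# Demo pipeline: synthetic XAO ensemble with the aqueous-solution basin
# populations as generator weights, full analysis at 300 K, and a Guinier
# fit of the 100-structure ensemble Debye profile.
peptide: xao

synthesis:
  n_frames: 18148          # 11 pairs/frame -> 199628 data points
  seed: 20180914
  jitter: uniform
  omega: 180.0
  basin_weights:
    PII: 0.534
    beta: 0.202
    alphaR: 0.126
    three10: 0.062
    alphaL: 0.041
    C7eq: 0.035

analysis:
  temperature: 300.0
  pairing: strict
  psi_cutoffs: [115.0]

scattering:
  n_structures: 100
  s_min: 0.001
  s_max: 0.05
  n_points: 100

output:
  ensemble_pdb_frames: 5
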