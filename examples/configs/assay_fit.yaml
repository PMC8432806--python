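# Generate a synthetic growth assay and fit it:
#   phenoswitch generate --config examples/configs/assay_fit.yaml --out assay.csv
#   phenoswitch fit --config examples/configs/assay_fit.yaml --data assay.csv --out fit.json
seed: 1
scenario: wt_like
assay:
  days: [1, 3, 5, 7]
  t_treat: 72.0
  cv: 0.10
  n_replicates: 3
fit:
  n_starts: 8
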