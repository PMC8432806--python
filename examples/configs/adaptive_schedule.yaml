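# Model-informed scheduling on the docetaxel-style stand-in parameters.
#   phenoswitch schedule --config examples/configs/adaptive_schedule.yaml --out out/
seed: 1
scenario: wt_like
therapy:
  candidates_days: [1, 2, 3, 4, 5, 6, 7]
  window_days: [50, 150]
  n0: 1.0e+5
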