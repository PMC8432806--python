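# Generic 21-day cyclic chemotherapy on the stay strategy (permanent
# resistance regime).
#   phenoswitch simulate --config examples/configs/cyclic_generic.yaml --out out/
seed: 1
scenario: stay
schedule:
  start_day: 50
  end_day: 275
  period_days: 21
  dose: 50.0
simulate:
  t_end_days: 350
  n0: 1.0e+5
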