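segments:
- t_start: 0.0
  t_end: inf
  dose: 10.0
inhibitors:
- time: 900.0
  target: EGFR
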