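segments:
- t_start: 0.0
  t_end: 0.5
  dose: 60.0
inhibitors: []
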