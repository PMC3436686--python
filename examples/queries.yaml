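queries:
  - source: EGF
    target: MAPK3
    max_length: 4
    required_node: EGFR
scaffold:
  chain: [EGF, EGFR, GRB2, SOS1, HRAS, RAF1, MAP2K1, MAPK3]
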