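{
  "duan": 1.204,
  "subgroup": {
    "IV": 1.0206,
    "SC": 1.3799,
    "IM": 1.0
  },
  "wooldridge": 1.0287,
  "worked_example_iv_factor": 1.0792,
  "selection_scores": {
    "normal_theory": 0.822675,
    "subgroup": 0.822382,
    "wooldridge": 0.822675
  },
  "preferred": "subgroup"
}
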