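{
  "variant": "CI2_eng",
  "chem": {
    "dG0": 10.9,
    "m_eq": 8.515625,
    "Cm": 1.28,
    "native": {"a": 1.0, "b": -0.01},
    "unfolded": {"a": 0.1, "b": 0.01}
  },
  "chevron": {
    "kf0": 25.0,
    "ku0": 0.58,
    "mf": -0.89,
    "mu": 0.52
  }
}
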