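{
  "variant": "CI2_wt",
  "chem": {
    "dG0": 30.9,
    "m_eq": 7.592137592137592,
    "Cm": 4.07,
    "native": {"a": 1.0, "b": -0.01},
    "unfolded": {"a": 0.1, "b": 0.01}
  },
  "chevron": {
    "kf0": 44.0,
    "ku0": 0.00019,
    "mf": -0.78,
    "mu": 0.51
  }
}
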