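{
  "variant": "CI2_1-58",
  "comment": "Tuning constants for the five-species scheme with C-peptide binding; qualitative fixture, not measured values.",
  "step_NS": {"Tm": 330.0, "dHm": 80.0, "dCp": 0.0},
  "step_NU": {"Tm": 335.0, "dHm": 260.0, "dCp": 0.0},
  "assoc_H": {"dG_ref": -176.0, "dH_ref": 100.0, "dCp": 0.0, "T_ref": 298.0, "stoichiometry": 6},
  "assoc_H2": {"dG_ref": -28.0, "dH_ref": 20.0, "dCp": 0.0, "T_ref": 298.0, "stoichiometry": 2},
  "bind_P": {"dG_ref": -19.0, "dH_ref": -30.0, "dCp": 0.0, "T_ref": 298.0, "stoichiometry": 1}
}
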