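{
  "name": "2 TMA + 3,5-DABA -> 3,5-DITA + 2 H2O",
  "stoichiometry": {"TMA": -2, "3,5-DABA": -1, "3,5-DITA": 1, "H2O": 2},
  "T": 298.15,
  "drS_J_molK": -44.72,
  "u_drS": 0.17
}
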