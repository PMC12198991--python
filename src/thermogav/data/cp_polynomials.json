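{
  "3,4-DABA": {"a3": -2.29e-7, "a2": -1.54e-4, "a1": 0.63, "a0": 0.59, "T_min": 298.15, "T_max": 613.15},
  "3,5-DABA": {"a3": -1.11e-7, "a2": -2.89e-4, "a1": 0.68, "a0": 1.10, "T_min": 298.15, "T_max": 613.15},
  "3,4-DITA": {"a3": 2.36e-7, "a2": -1.4e-7, "a2_alternative": -1.4e-3, "a1": 2.16, "a0": -40.24, "T_min": 298.15, "T_max": 613.15},
  "3,5-DITA": {"a3": 2.28e-7, "a2": -1.4e-7, "a2_alternative": -1.4e-3, "a1": 2.15, "a0": -38.07, "T_min": 298.15, "T_max": 613.15}
}
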