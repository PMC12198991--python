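[
  {"name": "TMA", "formula": "C9H4O5", "dfH_kJ_mol": -757.7, "u_dfH": null, "dfS_J_molK": null, "S_abs_J_molK": null},
  {"name": "3,4-DABA", "formula": "C7H8N2O2", "dfH_kJ_mol": -292.0, "u_dfH": 1.8, "dfS_J_molK": null, "S_abs_J_molK": null},
  {"name": "3,5-DABA", "formula": "C7H8N2O2", "dfH_kJ_mol": -289.0, "u_dfH": 1.8, "dfS_J_molK": null, "S_abs_J_molK": null},
  {"name": "3,4-DITA", "formula": "C25H12N2O10", "dfH_kJ_mol": -1406.6, "u_dfH": null, "dfS_J_molK": -1303.8, "S_abs_J_molK": null},
  {"name": "3,5-DITA", "formula": "C25H12N2O10", "dfH_kJ_mol": -1410.1, "u_dfH": null, "dfS_J_molK": -1295.6, "S_abs_J_molK": null},
  {"name": "H2O", "formula": "H2O", "dfH_kJ_mol": -241.826, "u_dfH": 0.040, "dfS_J_molK": null, "S_abs_J_molK": null}
]
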