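{
  "T": 298.15,
  "dita_formula": "C25H12N2O10",
  "dft_absolute_entropy": {
    "3,4-DITA": 836.9,
    "3,5-DITA": 846.0
  },
  "mlr_predictions": {
    "3,4-DITA": {"S": 839.8, "dfS": -1303.8, "dfG": -1017.9},
    "3,5-DITA": {"S": 848.0, "dfS": -1295.6, "dfG": -1023.8}
  },
  "auxiliary_enthalpies": {
    "benzene": {"dfH": 82.9, "u": 0.9},
    "o-phenylenediamine": {"dfH": 86.6, "u": 1.6},
    "m-phenylenediamine": {"dfH": 89.6, "u": 1.6},
    "benzoic acid": {"dfH": -295.7, "u": 0.1}
  },
  "reported_reaction_inputs": {
    "3,4-DITA": {"drH": -82.86, "u_drH": 2.06, "drS": -47.92, "u_drS": 0.17},
    "3,5-DITA": {"drH": -89.36, "u_drH": 2.06, "drS": -44.72, "u_drS": 0.17}
  }
}
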