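{
  "groups": {
    "CO-(O)(CO)": {"S": 9.79, "dfS": -28.16, "dfG": -79.72},
    "CO-(C_D)(O)": {"S": -0.17, "dfS": 6.5, "dfG": -20.23},
    "CO-(C)(O)": {"S": 13.61, "dfS": -24.34, "dfG": -79.44},
    "CO-(H)(O)": {"S": -32.67, "dfS": 77.16, "dfG": -181.71},
    "CO-(O)(C_B)": {"S": 18.43, "dfS": -47.22, "dfG": 23.22},
    "O-(H)(CO)": {"S": 8.98, "dfS": -16.06, "dfG": -337.89},
    "O-(C)(C_B)": {"S": 18.77, "dfS": -60.84, "dfG": -37.25},
    "C_D-(H)(CO)": {"S": 21.74, "dfS": -23.82, "dfG": -67.02},
    "C_B-(CO)(C_B)2": {"S": 41.55, "dfS": -78.55, "dfG": -21.67},
    "C_B-(O)(C_B)2": {"S": 18.77, "dfS": -60.84, "dfG": -37.25},
    "C-(CO)(C)3": {"S": 12.26, "dfS": -74.12, "dfG": 55.26},
    "C-(H)2(CO)(C)": {"S": 37.04, "dfS": -99.27, "dfG": -9.41},
    "C-(H)3(O)": {"S": 18.77, "dfS": -60.84, "dfG": -37.25},
    "C-(H)3(C)": {"S": -5.39, "dfS": 6.09, "dfG": -114.10},
    "C-(H)3(C_B)": {"S": 3.46, "dfS": 7.28, "dfG": -48.20},
    "C-(H)2(C)2": {"S": 31.12, "dfS": -105.19, "dfG": 10.78},
    "C_D-(H)2": {"S": -0.17, "dfS": 6.5, "dfG": -20.23},
    "C_B-(H)(C_B)2": {"S": 2.38, "dfS": 2.38, "dfG": -8.79},
    "C_B-(C)(C_B)2": {"S": 37.91, "dfS": -102.23, "dfG": 31.24},
    "C-(H)2(C)(C_B)": {"S": 34.45, "dfS": -109.51, "dfG": 79.44},
    "C-(C)4": {"S": 0.00, "dfS": 0.00, "dfG": 25.81},
    "CH3(qua)": {"S": 24.52, "dfS": -148.24, "dfG": 110.51},
    "C_B-(C_B)3": {"S": 18.22, "dfS": -58.55, "dfG": 40.84},
    "CO-(C)(N)": {"S": 12.21, "dfS": -14.54, "dfG": -153.75},
    "N-(H)(CO)2": {"S": -23.65, "dfS": 78.45, "dfG": -124.97},
    "C-(H)3(N)": {"S": -3.66, "dfS": 34.20, "dfG": -75.91},
    "N-(CO)2(C)": {"S": 21.61, "dfS": -50.46, "dfG": -36.18},
    "CO-(C_D)(N)": {"S": 21.91, "dfS": -30.32, "dfG": -46.79},
    "CO-(N)(C_B)": {"S": 23.12, "dfS": -31.33, "dfG": -44.89},
    "C_B-(NO2)(C_B)2": {"S": 58.75, "dfS": -176.76, "dfG": 57.45},
    "C-(H)2(N)(C)": {"S": 25.27, "dfS": -84.66, "dfG": 39.73},
    "C_B-(N)(C_B)2": {"S": 30.65, "dfS": -66.09, "dfG": 38.44},
    "N-(CO)2(C_B)": {"S": 30.65, "dfS": -66.09, "dfG": 38.44},
    "rsc": {"S": -20.22, "dfS": -20.22, "dfG": 4.19},
    "radical 1": {"S": 2.78, "dfS": 2.78, "dfG": -4.35},
    "radical 2": {"S": 0.32, "dfS": 0.32, "dfG": -3.34},
    "radical 3": {"S": -3.47, "dfS": -3.47, "dfG": -2.00},
    "radical 4": {"S": 0.86, "dfS": 0.86, "dfG": -1.81},
    "correction o-": {"S": -3.56, "dfS": -3.56, "dfG": 29.33},
    "correction m-": {"S": -1.91, "dfS": -1.91, "dfG": 14.90},
    "correction p-": {"S": -9.77, "dfS": -9.77, "dfG": 17.47}
  },
  "intercept": {"S": 272.69, "dfS": -153.46, "dfG": 168.44},
  "provenance": "MLR-refit Benson group values for gas-phase S (J/mol/K), dfS (J/mol/K) and dfG (kJ/mol) at 298.15 K, trained on a 77-molecule set of carboxylic acids and cyclic imides; table version 2025.1"
}
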