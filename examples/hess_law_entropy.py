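"""Entropy of formation via Hess's law, and enthalpy chaining.

Takes the DFT absolute entropies of the two diimidetricarboxylic acid
(DITA) isomers, subtracts the element reference entropies of C25H12N2O10,
and chains the resulting formation entropy with the regression-predicted
Gibbs energy to get an enthalpy of formation.
"""

from thermogav import (
    enthalpy_from_gibbs,
    formation_entropy,
    parse_formula,
    round_printed,
)
from thermogav.packaged import study_inputs

study = study_inputs()
formula = parse_formula(study["dita_formula"])

for isomer in ("3,4-DITA", "3,5-DITA"):
    s_abs = study["dft_absolute_entropy"][isomer]
    dfs = formation_entropy(s_abs, formula)
    dfg = study["mlr_predictions"][isomer]["dfG"]
    dfh = enthalpy_from_gibbs(dfg, dfs)
    print(
        f"{isomer}: S_abs = {s_abs:.1f} J/mol/K -> "
        f"dfS = {round_printed(dfs, 1):.1f} J/mol/K, "
        f"dfH = dfG + T*dfS = {round_printed(dfh, 1):.1f} kJ/mol"
    )

# dfS is the entropy change of forming the molecule from graphite and the
# diatomic gases; the large negative values reflect consuming ~14 mol of
# gas-phase elements per mole of product. dfH chains the two routes
# (DFT entropy + regression Gibbs energy) into one enthalpy.
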