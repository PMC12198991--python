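"""Reaction thermochemistry and equilibrium constants.

Evaluates the two gas-phase imide condensations
2 TMA + DABA -> DITA + 2 H2O at 298.15 K from the packaged species
enthalpies and reaction entropies.
"""

from thermogav import round_printed
from thermogav.packaged import reaction, species_table
from thermogav.reaction_thermo import reaction_report

species = species_table()
for isomer in ("3,4-DITA", "3,5-DITA"):
    rep = reaction_report(reaction(isomer), species)
    u = f" +/- {rep.u_drH:.2f}" if rep.u_drH else ""
    print(f"{rep.name}")
    print(f"  drH = {round_printed(rep.drH, 2):.2f}{u} kJ/mol")
    print(f"  drS = {rep.drS:.2f} J/mol/K")
    print(f"  drG = {round_printed(rep.drG, 2):.2f} kJ/mol")
    print(f"  Keq = {rep.keq:.3g}")

# Both condensations are exothermic and strongly product-favored at the
# standard state (Keq >> 1); the uncertainty is the root-sum-square of the
# stoichiometry-weighted species uncertainties.
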