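"""Group-additivity estimation from SMILES.

Perceives Benson groups for benzoic acid and a DITA isomer, annotates
aromatic substitution corrections, and estimates S°, ΔfS° and ΔfG° with
the packaged group-value table.
"""

from thermogav import estimate, round_printed
from thermogav.group_perception import (
    annotate_substitution_corrections,
    from_smiles,
    perceive_groups,
)
from thermogav.packaged import gav_table

DITA_34 = (
    "OC(=O)c1ccc(N2C(=O)c3ccc(C(=O)O)cc3C2=O)"
    "c(N2C(=O)c3ccc(C(=O)O)cc3C2=O)c1"
)

table = gav_table()
for name, smiles in [("benzoic acid", "OC(=O)c1ccccc1"), ("3,4-DITA", DITA_34)]:
    mol = from_smiles(smiles)
    gv = annotate_substitution_corrections(mol, perceive_groups(mol))
    print(f"{name}:")
    for label, n in sorted(gv.to_dict().items()):
        print(f"  {label}: {n:g}")
    for prop, unit in (("S", "J/mol/K"), ("dfS", "J/mol/K"), ("dfG", "kJ/mol")):
        val = estimate(gv, table, prop)
        print(f"  {prop} = {round_printed(val, 1):.1f} {unit}")

# Each estimate is intercept + sum(count * group value); the correction
# rows (rsc per imide ring, o-/m-/p- per substituent pair) enter the sum
# like ordinary groups.
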