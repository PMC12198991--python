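# thermogav

Benson group-additivity thermochemistry for gas-phase C/H/N/O molecules:
estimation of absolute entropy (S°), entropy of formation (ΔfS°) and Gibbs
energy of formation (ΔfG°) at 298.15 K, with the supporting Hess's-law and
Gibbs-relation algebra, least-squares refitting of group values, functional
group perception from SMILES, reaction equilibrium constants, and cubic
heat-capacity polynomials.

The package is aimed at thermochemists and process modellers who need
formation properties for molecules — particularly carboxylic acids and
cyclic imides such as the diimidetricarboxylic acids (DITAs,
C₂₅H₁₂N₂O₁₀) — without running electronic-structure calculations for each
one.

## The model

A molecule is decomposed into Benson groups: each heavy atom is a center
labelled by its type (sp³ `C`, aromatic `C_B`, olefinic `C_D`, carbonyl
`CO` carrying its doubly bonded oxygen, `O`, `N`) and the types of its
neighbours, e.g. `C_B-(H)(C_B)2` for an aromatic CH. A property is
estimated linearly,

    X(molecule) = x0 + Σ_g  n_g · x_g ,

where `n_g` counts group *g* (including additive corrections: `rsc` per
five-membered imide ring and `correction o-/m-/p-` per aromatic substituent
pair) and the values `x_g` plus intercept `x0` come from a multiple linear
regression over a reference set of 77 acids and imides; the refit table is
packaged (`thermogav.packaged.gav_table()`).

Around the group model sit the exact thermodynamic identities:

* Hess's law: `ΔfS° = S°(molecule) − [m·S°(C,s) + n/2·S°(H₂) + p/2·S°(O₂) + o/2·S°(N₂)]`
* Gibbs relation: `ΔfG° = ΔfH° − T·ΔfS°` (and its inverse, used to chain a
  regression ΔfG° with an independently computed entropy into ΔfH°)
* reactions: `ΔrX = Σ νᵢ ΔfXᵢ` and `K_eq = exp(−ΔrG°/RT)`
* uncertainty combination by root sum of squares.

## Worked example

```python
from thermogav import formation_entropy, enthalpy_from_gibbs, parse_formula, round_printed

dita = parse_formula("C25H12N2O10")
dfs = formation_entropy(836.9, dita)          # DFT absolute entropy in, J/mol/K
dfh = enthalpy_from_gibbs(-1017.9, dfs)       # chain with regression dfG, kJ/mol
print(round_printed(dfs, 1), round_printed(dfh, 1))
```

prints `-1306.7 -1407.5`: forming one mole of the 3,4-DITA isomer from
graphite and the elemental gases loses ≈1306.7 J mol⁻¹ K⁻¹ of entropy
(≈14 mol of gas consumed per mole of product), and combining that entropy
with the regression Gibbs energy gives a formation enthalpy of
−1407.5 kJ mol⁻¹.

Reaction equilibrium for the solvent-free imide condensation
`2 TMA + 3,4-DABA → 3,4-DITA + 2 H₂O` (see `examples/reaction_equilibrium.py`):

```
drH = -82.85 +/- 1.80 kJ/mol
drS = -47.92 J/mol/K
drG = -68.56 kJ/mol
Keq = 1.03e+12
```

— the gas-phase condensation is exothermic and strongly product-favored at
298.15 K. The `examples/` directory has one short script per capability
(estimation from SMILES, Hess's-law chaining, reaction equilibria, group
value refitting on synthetic data, heat-capacity polynomials); each prints
its numbers with a line on what they mean. A thin CLI mirrors the library:
`thermogav hess|gibbs|estimate|perceive|fit|react|cp|simulate --help`.

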