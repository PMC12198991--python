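# Methods

## Scope and model

`thermogav` implements linear group-contribution (Benson group additivity)
estimation of gas-phase standard thermochemistry at 298.15 K and 0.1 MPa
for closed-shell, neutral C/H/N/O molecules, together with the exact
thermodynamic algebra that connects the estimated quantities: Hess's-law
formation entropies, the Gibbs relation and its inverse, reaction sums and
equilibrium constants, and root-sum-square (RSS) uncertainty combination.
The group-contribution part is statistical; everything else is identity
arithmetic, and the two are kept strictly separate in the code.

## Units, constants and rounding

Entropies are J mol⁻¹ K⁻¹; enthalpies and Gibbs energies are kJ mol⁻¹,
matching how thermochemical tables print them. The mixed-unit factor of
1000 in `G = H − T·S/1000` lives in exactly two functions
(`gibbs_of_formation`, `enthalpy_from_gibbs`) and their reaction-level
analogue; no other code converts units. R = 8.314462618 J mol⁻¹ K⁻¹
(CODATA 2018); T defaults to 298.15 K and is overridable everywhere.
Element reference entropies default to S°(C, graphite) = 5.74 ± 0.10,
S°(H₂) = 130.571 ± 0.003, S°(O₂) = 205.043 ± 0.005,
S°(N₂) = 191.500 ± 0.004 J mol⁻¹ K⁻¹; all four are user-overridable via a
JSON config block. Element-entropy uncertainties are carried but only
propagated by the explicit opt-in helper. Comparisons against printed
table values round half-away-from-zero to the printed decimals
(`round_printed`), which is how such tables are rounded; Python's default
banker's rounding would disagree on exact halves.

## The group-value table

The packaged table (`data/benson_gav_mlr.json`, version 2025.1) holds 41
group and correction rows plus an intercept row, each with values for S°,
ΔfS° and ΔfG°. Design choices:

* **Canonical labels.** Grammar `CENTER-(LIG)(LIG)n…` with centers
  {C, C_D, C_B, CO, O, N} and ligands sorted by the fixed priority
  CO, C_B, C_D, C, N, O, H. Published spellings (which put H first, e.g.
  `C-(H)2(CO)(C)`) are registered as aliases; `GroupVector` canonicalizes
  its keys on construction so either spelling is accepted and compares
  equal. Two table rows (`CH3(qua)`, `C_B-(NO2)(C_B)2`) fall outside the
  grammar and are stored verbatim.
* **Aliased value triples.** Three rows (`C-(H)3(O)`, `O-(C)(C_B)`,
  `C_B-(O)(C_B)2`) share one value triple, as do `C_B-(N)(C_B)2` and
  `N-(CO)2(C_B)`, and two more pairs. They are kept as distinct labels;
  the coincidence is most plausibly collinearity in the source fit (those
  groups co-occur in the training molecules), not a chemical statement.
* **Corrections.** `rsc` is a ring-strain correction applied once per
  five-membered imide ring; `correction o-/m-/p-` are applied once per
  unordered pair of substituted positions on an aromatic six-ring,
  classified by ring distance (1/2/3). The four `radical 1–4` rows are
  loadable and usable in estimation but never assigned by perception: the
  training domain is closed-shell, and their intended semantics are not
  documented in the source.
* **Intercept.** Added exactly once per molecule — the table is the
  coefficient vector of a regression fit *with* intercept, so a group sum
  without it is meaningless.

The estimate is linear by construction:
`estimate(g1+g2) = estimate(g1) + estimate(g2) − intercept`.

## Group perception

Perception runs on a plain heavy-atom graph (elements, implicit-H counts,
aromatic flags, bond orders); SMILES input is converted by RDKit, and
aromaticity is taken from the input flags — no independent aromatic
perception. Center typing: carbon double-bonded to O → `CO` (the carbonyl
O is absorbed, never a center); aromatic carbon → `C_B`; other sp² carbon
→ `C_D`; sp³ carbon → `C`; O and N are centers. Carboxylic acids are
therefore `CO-(O)(X)` + `O-(H)(CO)`. An imide nitrogen bonded to two CO
and an aromatic carbon maps to `N-(CO)2(C_B)`; with an sp³ carbon,
`N-(CO)2(C)`. Exactly one group is emitted per heavy atom (atom
conservation is property-tested: the formula implied by the group vector
must equal the molecular formula, including for both DITA isomers at
C₂₅H₁₂N₂O₁₀).

Substitution corrections are a separate pass so the caller controls them.
Every unordered pair of substituted positions in each aromatic six-ring is
counted — not only adjacent pairs — because that rule is deterministic and
matches standard group-additivity practice; a position counts as
substituted when it has any heavy-atom neighbour outside the ring, which
deliberately includes ring-fusion attachments. Groups that perception
emits but the active table lacks fail at estimation time (with all missing
labels listed), not at perception time, so a vector can be inspected or
refit even when the table is incomplete.

Known limitation: the published per-molecule correction assignments for
the DITA isomers are not available, so the packaged table plus automatic
perception does not reproduce the published DITA-specific estimates; with
zero corrections both isomers would get identical group sums, and the
automatic o/m/p assignment is this package's own convention. The DITA
chain results shipped here therefore use the published regression
*predictions* as inputs rather than re-deriving them from group counts.

## Regression pipeline

Plain ordinary least squares (no regularization) of each property
independently on the count matrix plus an intercept column, solved by
`numpy.linalg.lstsq`. Rank-deficient designs get the minimum-norm solution
and a warning naming the aliased columns (found by incremental rank
checks, adequate at these matrix sizes); predictions are invariant to the
aliasing. Holdout evaluation uses a single uniform split without
replacement, train size `floor(train_frac·n)`, no stratification; default
`train_frac = 0.7`, seed 42, both always recorded in the fit result.
Metrics: R² = 1 − SS_res/SS_tot, MAE, RMSE; a zero-variance observation
vector is an error rather than a NaN R². ΔfG° is fit directly as its own
regression (not derived from the other two), though nothing prevents a
user from chaining instead.

A structural identity worth knowing: when ΔfS° observations differ from S°
observations by an exact linear function of the design (which is true
whenever both derive from the same molecules via Hess's law, since the
element-entropy sum is linear in group counts), the two fits have
*identical* residuals — identical MAE and RMSE, different R² (ΔfS° has far
more variance to explain). The synthetic generator preserves this
structure and the suite asserts it to ~1e−9 relative (exact in exact
arithmetic; OLS is solved in floating point).

## Synthetic data generator

The generator emulates the statistical shape of a reference thermochemistry
dataset — 77 molecules by default, over the packaged 41-label vocabulary —
without generating chemical structures: counts are Poisson(0.6) per group
truncated at 4 (sparse functional-group incidence), with one guaranteed
occurrence per group and a nonempty guarantee per row so every coefficient
is identifiable at sufficient n. Observations are
`S = truth·counts + N(0, σ_S)`, `ΔfS = S_obs − element-entropy sum of the
implied formula` (exactly, see above), and `ΔfG = truth·counts + N(0, σ_G)`;
defaults σ_S = 5 J mol⁻¹ K⁻¹ and σ_G = 5 kJ mol⁻¹, the order of the
published fit residuals. Because the published table's ΔfS° column was fit
separately, it is not group-by-group consistent with its S° column; the
generator therefore derives a consistent ΔfS° truth column
(`S°_g − element sum of group g's atoms`) so that noiseless data is exactly
reproduced by `estimate` for all three properties. Everything is
deterministic given the seed. What passing these tests shows: the pipeline
recovers a linear truth under the stated noise (coefficient RMSE < 1
J mol⁻¹ K⁻¹ at σ = 5, n = 500) and honors the shared-residual identity.
What it does not show: performance on real molecules, where group counts
are strongly collinear and the linear model itself is an approximation.

## Reactions

`Reaction` is a signed stoichiometry map; ΔrH and ΔrS are stoichiometric
sums over species formation values, ΔrG the Gibbs relation, and
`K_eq = exp(−1000·ΔrG/(R·T))` with an overflow guard at |exponent| ≈ 700
(returns ±inf/0 with a warning). ΔrH uncertainty is the RSS of
|ν_i|·u_i with unreported uncertainties contributing zero — so the
computed uncertainty is a floor, not the published combined value, which
cannot be decomposed from printed inputs. The packaged condensation
reactions carry the reaction entropy (and its uncertainty) as
reaction-level inputs because the per-species formation entropies of TMA,
the DABAs and water are not printed in the source; when a species table
does contain all ΔfS values, the species route is preferred automatically.

## Heat-capacity polynomials

`Cp(T) = a₃T³ + a₂T² + a₁T + a₀` (J mol⁻¹ K⁻¹). Fitting uses
`numpy.polyfit` with ≥ 4 distinct temperatures required. The packaged
coefficient sets cover both DABA and both DITA isomers; their validity
range 298.15–613.15 K is this package's convention (the calorimetric scan
range), not a source statement. The two DITA sets print their quadratic
coefficient in a form ("0.0014×10⁻⁴") whose magnitude is suspicious next
to the DABA sets (~10⁻⁴): the packaged default is the literal printed
value −1.4×10⁻⁷ with a warning on load, and `reading="alternative"`
selects the annotated alternative −1.4×10⁻³. No downstream result in this
package depends on the choice.

## Problem sizes

The test suite and the acceptance script use synthetic datasets of n = 77
(the reference-set size), n = 150–200 for noiseless closure checks, and
n = 500 for parameter-recovery statistics; all complete in seconds. The
thermochemical identity checks are closed-form and instantaneous.
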