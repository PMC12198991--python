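"""Hess's-law and Gibbs-relation algebra for formation thermochemistry.

Conventions used throughout the package:

* enthalpies and Gibbs energies in kJ mol^-1,
* entropies in J mol^-1 K^-1,
* temperature in K (default 298.15 K, 0.1 MPa standard state).

The mixed-unit Gibbs relation dG = dH - T*dS/1000 is owned by exactly two
functions here (:func:`gibbs_of_formation` and its inverse); no other module
performs the kJ/J conversion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .chem_core import (
    Constants,
    DEFAULT_CONSTANTS,
    ElementalFormula,
    T_REF,
    element_entropy_sum,
    parse_formula,
)

__all__ = [
    "SpeciesThermo",
    "formation_entropy",
    "gibbs_of_formation",
    "enthalpy_from_gibbs",
    "enthalpic_difference_estimate",
    "isomerization_enthalpy",
    "combine_rss",
    "round_printed",
    "load_species_table",
    "save_species_table",
]

_CSV_COLUMNS = ["name", "formula", "dfH_kJ_mol", "u_dfH", "dfS_J_molK", "S_abs_J_molK"]


def round_printed(x: float, decimals: int) -> float:
    """Round half-away-from-zero to a fixed number of decimals.

    Matches how printed thermochemical tables round (1306.75 -> 1306.8,
    -1306.75 -> -1306.8), unlike banker's rounding.
    """
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
    return float(d.copy_negate() if x < 0 else d)


@dataclass
class SpeciesThermo:
    """Per-species standard thermochemistry at the reference temperature.

    At least one of ``dfH`` (kJ mol^-1), ``dfS`` (J mol^-1 K^-1) or ``S_abs``
    (J mol^-1 K^-1) must be present. When all of ``dfS``, ``S_abs`` and
    ``formula`` are given, they must satisfy the Hess's-law identity
    dfS = S_abs - element_entropy_sum(formula) within 0.05 J mol^-1 K^-1.
    """

    name: str
    dfH: Optional[float] = None
    dfS: Optional[float] = None
    S_abs: Optional[float] = None
    u_dfH: Optional[float] = None
    formula: Optional[ElementalFormula] = None

    def __post_init__(self):
        if self.dfH is None and self.dfS is None and self.S_abs is None:
            raise ValueError(f"species {self.name!r} has no thermochemical data")
        if (
            self.dfS is not None
            and self.S_abs is not None
            and self.formula is not None
        ):
            implied = self.S_abs - element_entropy_sum(self.formula)
            if abs(implied - self.dfS) > 0.05:
                raise ValueError(
                    f"species {self.name!r}: dfS={self.dfS} inconsistent with "
                    f"S_abs - S(elements) = {implied:.4f} (tolerance 0.05)"
                )

    def with_derived_dfS(self, constants: Constants = DEFAULT_CONSTANTS) -> "SpeciesThermo":
        """Fill dfS from S_abs and formula if absent."""
        if self.dfS is not None or self.S_abs is None or self.formula is None:
            return self
        return SpeciesThermo(
            name=self.name,
            dfH=self.dfH,
            dfS=formation_entropy(self.S_abs, self.formula, constants),
            S_abs=self.S_abs,
            u_dfH=self.u_dfH,
            formula=self.formula,
        )


def formation_entropy(
    S_abs: float,
    formula: ElementalFormula,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Entropy of formation from absolute entropy via Hess's law.

    dfS = S_abs(compound) - sum of element reference entropies, both in
    J mol^-1 K^-1. Zero for an element in its reference state.
    """
    if S_abs <= 0:
        raise ValueError(f"absolute entropy must be positive, got {S_abs}")
    return S_abs - element_entropy_sum(formula, constants)


def gibbs_of_formation(dfH: float, dfS: float, T: float = T_REF) -> float:
    """Gibbs energy of formation, kJ mol^-1: dfG = dfH - T*dfS/1000.

    ``dfH`` in kJ mol^-1, ``dfS`` in J mol^-1 K^-1.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return dfH - T * dfS / 1000.0


def enthalpy_from_gibbs(dfG: float, dfS: float, T: float = T_REF) -> float:
    """Invert the Gibbs relation: dfH = dfG + T*dfS/1000 (kJ mol^-1).

    Used to chain a regression-predicted dfG with an independently computed
    entropy of formation into an enthalpy of formation.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return dfG + T * dfS / 1000.0


def enthalpic_difference_estimate(
    parent_dfH: float, analog_dfH: float, reference_dfH: float
) -> float:
    """Estimate a formation enthalpy by transferring a substituent increment.

    Returns parent + (analog - reference): e.g. benzoic acid plus the
    (phenylenediamine - benzene) increment estimates a diaminobenzoic acid.
    All three values on the same scale (kJ mol^-1).
    """
    return parent_dfH + (analog_dfH - reference_dfH)


def isomerization_enthalpy(dfH_a: float, dfH_b: float) -> float:
    """Enthalpy of the isomerization b -> a: dfH_a - dfH_b (kJ mol^-1)."""
    return dfH_a - dfH_b


def combine_rss(uncertainties: Sequence[float]) -> float:
    """Combined standard uncertainty: root sum of squares.

    All entries must be nonnegative; an empty list is an error (there is
    nothing to combine).
    """
    vals = list(uncertainties)
    if not vals:
        raise ValueError("cannot combine an empty list of uncertainties")
    if any(u < 0 for u in vals):
        raise ValueError("uncertainties must be nonnegative")
    return math.sqrt(sum(u * u for u in vals))


# ---------------------------------------------------------------------------
# species-table IO


def _species_to_record(sp: SpeciesThermo) -> dict:
    return {
        "name": sp.name,
        "formula": sp.formula.to_string() if sp.formula else None,
        "dfH_kJ_mol": sp.dfH,
        "u_dfH": sp.u_dfH,
        "dfS_J_molK": sp.dfS,
        "S_abs_J_molK": sp.S_abs,
    }


def _species_from_record(rec: Mapping) -> SpeciesThermo:
    def _num(key):
        v = rec.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    formula = rec.get("formula")
    if isinstance(formula, float) and math.isnan(formula):
        formula = None
    return SpeciesThermo(
        name=str(rec["name"]),
        dfH=_num("dfH_kJ_mol"),
        u_dfH=_num("u_dfH"),
        dfS=_num("dfS_J_molK"),
        S_abs=_num("S_abs_J_molK"),
        formula=parse_formula(formula) if formula else None,
    )


def load_species_table(path) -> dict[str, SpeciesThermo]:
    """Read a species table from CSV or JSON (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        if isinstance(records, Mapping):
            records = [{"name": k, **v} for k, v in records.items()]
    else:
        records = pd.read_csv(path).to_dict(orient="records")
    out = {}
    for rec in records:
        sp = _species_from_record(rec)
        if sp.name in out:
            raise ValueError(f"duplicate species name {sp.name!r}")
        out[sp.name] = sp
    return out


def save_species_table(species: Iterable[SpeciesThermo], path) -> None:
    path = Path(path)
    records = [_species_to_record(sp) for sp in species]
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2)
    else:
        pd.DataFrame(records, columns=_CSV_COLUMNS).to_csv(path, index=False)
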