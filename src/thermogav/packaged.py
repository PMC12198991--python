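"""Accessors for the datasets shipped with the package.

Everything here is plain JSON under ``thermogav/data``: the MLR-refit Benson
group-value table, the formation thermochemistry of the imide-condensation
species, the two condensation reactions, the cubic Cp coefficient sets and
the study input numbers used by the worked examples.
"""

from __future__ import annotations

import json
from importlib import resources

from .gav_model import GavParameterTable, builtin_table
from .hess_gibbs import SpeciesThermo, _species_from_record
from .reaction_thermo import Reaction, packaged_reaction
from .cp_poly import CpPolynomial, packaged_cp, packaged_cp_names

__all__ = [
    "gav_table",
    "species_table",
    "reaction",
    "cp_polynomial",
    "cp_names",
    "study_inputs",
]


def _read(resource: str):
    with resources.files("thermogav.data").joinpath(resource).open() as fh:
        return json.load(fh)


def gav_table() -> GavParameterTable:
    """The packaged MLR-refit Benson group-value table."""
    return builtin_table()


def species_table() -> dict[str, SpeciesThermo]:
    """Formation thermochemistry of TMA, the DABAs, the DITAs and water."""
    records = _read("species_dita_synthesis.json")
    return {rec["name"]: _species_from_record(rec) for rec in records}


def reaction(name: str) -> Reaction:
    """A packaged condensation reaction, ``"3,4-DITA"`` or ``"3,5-DITA"``."""
    return packaged_reaction(name)


def cp_polynomial(name: str, reading: str = "as_printed") -> CpPolynomial:
    return packaged_cp(name, reading=reading)


def cp_names() -> list[str]:
    return packaged_cp_names()


def study_inputs() -> dict:
    """Input numbers of the reference study (DFT entropies, regression
    predictions, auxiliary enthalpies, reported reaction quantities)."""
    return _read("dita_study_inputs.json")
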