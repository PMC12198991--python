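"""Reaction-level thermochemistry and equilibrium constants.

A gas-phase reaction is a signed stoichiometry map (reactants negative,
products positive); ΔrH and ΔrS are stoichiometric sums of species
formation quantities, ΔrG follows the Gibbs relation and

    Keq = exp(-1000 * ΔrG / (R * T))

with ΔrG in kJ mol^-1. The packaged reaction files describe the imide
condensations 2 TMA + DABA -> DITA + 2 H2O.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

from .chem_core import Constants, DEFAULT_CONSTANTS, T_REF
from .hess_gibbs import SpeciesThermo, combine_rss

__all__ = [
    "Reaction",
    "reaction_enthalpy",
    "reaction_entropy",
    "reaction_gibbs",
    "equilibrium_constant",
    "reaction_enthalpy_uncertainty",
    "ReactionReport",
    "reaction_report",
    "load_reaction",
    "packaged_reaction",
]

_EXP_GUARD = 700.0  # beyond this the exponent overflows float64


@dataclass(frozen=True)
class Reaction:
    """Signed stoichiometry (reactants < 0 < products) and temperature."""

    stoichiometry: Mapping[str, float]
    temperature: float = T_REF
    name: str = ""
    # reaction-level inputs for when per-species data is unavailable
    drS: Optional[float] = None
    u_drS: Optional[float] = None
    u_drH: Optional[float] = None

    def __post_init__(self):
        coeffs = dict(self.stoichiometry)
        if any(v == 0 for v in coeffs.values()):
            raise ValueError("stoichiometric coefficients must be nonzero")
        if not any(v < 0 for v in coeffs.values()) or not any(
            v > 0 for v in coeffs.values()
        ):
            raise ValueError("a reaction needs at least one reactant and one product")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "stoichiometry", coeffs)

    def reversed(self) -> "Reaction":
        return Reaction(
            {k: -v for k, v in self.stoichiometry.items()},
            self.temperature,
            name=f"reverse({self.name})" if self.name else "",
            drS=None if self.drS is None else -self.drS,
            u_drS=self.u_drS,
            u_drH=self.u_drH,
        )


def _stoich_sum(rxn: Reaction, thermo: Mapping[str, SpeciesThermo], attr: str) -> float:
    total = 0.0
    for name, nu in rxn.stoichiometry.items():
        if name not in thermo:
            raise KeyError(f"species {name!r} missing from thermochemistry table")
        value = getattr(thermo[name], attr)
        if value is None:
            raise ValueError(f"species {name!r} has no {attr}")
        total += nu * value
    return total


def reaction_enthalpy(rxn: Reaction, thermo: Mapping[str, SpeciesThermo]) -> float:
    """ΔrH = Σ ν_i ΔfH_i, kJ mol^-1."""
    return _stoich_sum(rxn, thermo, "dfH")


def reaction_entropy(rxn: Reaction, thermo: Mapping[str, SpeciesThermo]) -> float:
    """ΔrS = Σ ν_i ΔfS_i, J mol^-1 K^-1."""
    return _stoich_sum(rxn, thermo, "dfS")


def reaction_gibbs(drH: float, drS: float, T: float = T_REF) -> float:
    """ΔrG = ΔrH − T·ΔrS/1000, kJ mol^-1 (ΔrS in J mol^-1 K^-1)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return drH - T * drS / 1000.0


def equilibrium_constant(
    drG: float, T: float = T_REF, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Dimensionless standard-state Keq = exp(−1000·ΔrG/(R·T)).

    Exponents beyond ~700 overflow and return ±inf/0 with a warning.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    x = -1000.0 * drG / (constants.R * T)
    if x > _EXP_GUARD:
        warnings.warn(f"Keq exponent {x:.1f} overflows; returning +inf", stacklevel=2)
        return math.inf
    if x < -_EXP_GUARD:
        warnings.warn(f"Keq exponent {x:.1f} underflows; returning 0", stacklevel=2)
        return 0.0
    return math.exp(x)


def reaction_enthalpy_uncertainty(
    rxn: Reaction, thermo: Mapping[str, SpeciesThermo]
) -> float:
    """RSS combination of |ν_i|·u(ΔfH_i); species without a printed
    uncertainty contribute zero."""
    terms = [
        abs(nu) * (thermo[name].u_dfH or 0.0)
        for name, nu in rxn.stoichiometry.items()
        if name in thermo
    ]
    return combine_rss(terms) if terms else 0.0


@dataclass
class ReactionReport:
    name: str
    temperature: float
    drH: float
    drS: Optional[float]
    drG: Optional[float]
    keq: Optional[float]
    u_drH: Optional[float] = None
    u_drS: Optional[float] = None
    u_drG: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "name", "temperature", "drH", "drS", "drG", "keq",
            "u_drH", "u_drS", "u_drG",
        )}


def reaction_report(
    rxn: Reaction,
    thermo: Mapping[str, SpeciesThermo],
    constants: Constants = DEFAULT_CONSTANTS,
) -> ReactionReport:
    """Full ΔrH/ΔrS/ΔrG/Keq report with RSS-combined uncertainties.

    ΔrS comes from species ΔfS values when all are present, otherwise from
    the reaction's own ``drS`` field (reference datasets often print the
    reaction entropy without its per-species decomposition).
    """
    T = rxn.temperature
    drH = reaction_enthalpy(rxn, thermo)
    u_drH = rxn.u_drH
    if u_drH is None:
        u = reaction_enthalpy_uncertainty(rxn, thermo)
        u_drH = u if u > 0 else None
    try:
        drS = reaction_entropy(rxn, thermo)
    except (KeyError, ValueError):
        drS = rxn.drS
    drG = keq = u_drG = None
    if drS is not None:
        drG = reaction_gibbs(drH, drS, T)
        keq = equilibrium_constant(drG, T, constants)
        parts = [u for u in (u_drH, (rxn.u_drS or 0) * T / 1000.0) if u]
        u_drG = combine_rss(parts) if parts else None
    return ReactionReport(
        name=rxn.name, temperature=T, drH=drH, drS=drS, drG=drG, keq=keq,
        u_drH=u_drH, u_drS=rxn.u_drS, u_drG=u_drG,
    )


# ---------------------------------------------------------------------------
# IO


def _reaction_from_dict(d: Mapping) -> Reaction:
    return Reaction(
        stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
        temperature=float(d.get("T", T_REF)),
        name=str(d.get("name", "")),
        drS=None if d.get("drS_J_molK") is None else float(d["drS_J_molK"]),
        u_drS=None if d.get("u_drS") is None else float(d["u_drS"]),
        u_drH=None if d.get("u_drH") is None else float(d["u_drH"]),
    )


def load_reaction(path) -> Reaction:
    """Read a reaction JSON: {"stoichiometry": {...}, "T": 298.15, ...}."""
    with open(Path(path)) as fh:
        return _reaction_from_dict(json.load(fh))


def packaged_reaction(name: str) -> Reaction:
    """Load a packaged reaction by name (``"3,4-DITA"`` or ``"3,5-DITA"``)."""
    key = name.replace(",", "").replace("-", "_").lower()
    resource = f"reaction_{key}.json"
    path = resources.files("thermogav.data").joinpath(resource)
    if not path.is_file():
        raise KeyError(f"no packaged reaction {name!r}")
    with path.open() as fh:
        return _reaction_from_dict(json.load(fh))
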