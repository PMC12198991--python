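"""Benson group-additivity estimation of S°, ΔfS° and ΔfG°.

A molecule is featurized as counts of Benson groups — a heavy-atom center
plus the types of its bonded neighbors, e.g. ``C_B-(H)(C_B)2`` for an
aromatic CH carbon — plus counts of additive correction terms (ring strain,
ortho/meta/para substitution). A property estimate is

    intercept + sum_g count(g) * value(g, property)

with per-group values obtained by multiple linear regression on a reference
dataset; the packaged table covers carboxylic acids and cyclic imides.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, NamedTuple, Optional

from .chem_core import ElementalFormula

__all__ = [
    "GroupVector",
    "GroupValues",
    "GavParameterTable",
    "GroupAtomMap",
    "canonical_label",
    "estimate",
    "formula_from_groups",
    "builtin_table",
    "load_table",
    "save_table",
    "CORRECTION_LABELS",
    "PROPERTIES",
]

PROPERTIES = ("S", "dfS", "dfG")

#: Additive correction terms: ring strain of the five-membered imide ring,
#: the table's four (unassigned) radical rows, and the aromatic
#: ortho/meta/para substitution-pattern corrections.
CORRECTION_LABELS = frozenset(
    {
        "rsc",
        "radical 1",
        "radical 2",
        "radical 3",
        "radical 4",
        "correction o-",
        "correction m-",
        "correction p-",
    }
)

_CENTERS = ("CO", "C_B", "C_D", "C", "O", "N")
# ligand sort priority; lower index sorts first
_LIGAND_PRIORITY = {t: i for i, t in enumerate(("CO", "C_B", "C_D", "C", "N", "O", "H"))}
_LIGAND_RE = re.compile(r"\(([^()]+)\)(\d*)")


def _parse_group_label(label: str):
    """Parse ``CENTER-(LIG)(LIG)n...``; return (center, {ligand: count}) or None."""
    head, sep, tail = label.partition("-")
    if not sep or head not in _CENTERS:
        return None
    ligands: dict[str, int] = {}
    pos = 0
    for m in _LIGAND_RE.finditer(tail):
        if m.start() != pos:
            return None
        lig, mult = m.group(1), int(m.group(2) or 1)
        if lig not in _LIGAND_PRIORITY:
            return None
        ligands[lig] = ligands.get(lig, 0) + mult
        pos = m.end()
    if pos != len(tail) or not ligands:
        return None
    return head, ligands


def _format_group_label(center: str, ligands: Mapping[str, int]) -> str:
    parts = []
    for lig in sorted(ligands, key=_LIGAND_PRIORITY.__getitem__):
        n = ligands[lig]
        parts.append(f"({lig}){n if n > 1 else ''}")
    return f"{center}-{''.join(parts)}"


def canonical_label(label: str) -> str:
    """Canonicalize a group label; unparseable labels pass through stripped.

    Ligands are sorted by the fixed priority CO, C_B, C_D, C, N, O, H and
    repeats collapsed with a multiplicity suffix, so ``C_B-(H)(C_B)2`` and
    ``C_B-(C_B)2(H)`` denote the same group. Correction labels and the few
    table rows outside the grammar (e.g. ``CH3(qua)``) are kept verbatim.
    """
    label = label.strip()
    parsed = _parse_group_label(label)
    if parsed is None:
        return label
    return _format_group_label(*parsed)


class GroupValues(NamedTuple):
    """Per-group increments: S and dfS in J mol^-1 K^-1, dfG in kJ mol^-1."""

    S: float
    dfS: float
    dfG: float


@dataclass(frozen=True)
class GroupVector:
    """Counts of Benson groups plus counts of correction terms.

    Keys are canonicalized on construction; correction labels supplied in
    ``counts`` are routed into ``corrections`` automatically, so
    ``GroupVector({"C_B-(H)(C_B)2": 6, "rsc": 1})`` is valid.
    """

    counts: Mapping[str, float] = field(default_factory=dict)
    corrections: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        groups: dict[str, float] = {}
        corr: dict[str, int] = {}
        for label, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {label!r}")
            if n == 0:
                continue
            canon = canonical_label(label)
            if canon in CORRECTION_LABELS:
                corr[canon] = corr.get(canon, 0) + int(n)
            else:
                groups[canon] = groups.get(canon, 0) + n
        for label, n in self.corrections.items():
            canon = canonical_label(label)
            if canon not in CORRECTION_LABELS:
                raise ValueError(f"unknown correction label {label!r}")
            if n < 0:
                raise ValueError(f"negative count for {label!r}")
            if n:
                corr[canon] = corr.get(canon, 0) + int(n)
        object.__setattr__(self, "counts", groups)
        object.__setattr__(self, "corrections", corr)

    def all_counts(self) -> dict[str, float]:
        """Merged group + correction counts (corrections are additive terms)."""
        merged = dict(self.counts)
        merged.update(self.corrections)
        return merged

    def __add__(self, other: "GroupVector") -> "GroupVector":
        merged = dict(self.all_counts())
        for k, v in other.all_counts().items():
            merged[k] = merged.get(k, 0) + v
        return GroupVector(merged)

    def __bool__(self) -> bool:
        return bool(self.counts) or bool(self.corrections)

    def to_dict(self) -> dict[str, float]:
        return self.all_counts()

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "GroupVector":
        return cls(counts=dict(d))


@dataclass
class GavParameterTable:
    """Group-additivity values for S°, ΔfS° and ΔfG° plus the fit intercept.

    ``values`` is keyed by canonical label; ``aliases`` maps alternative
    spellings (e.g. the published table's verbatim labels) onto canonical
    ones. The intercept is the regression's constant term, added exactly
    once per molecule.
    """

    values: dict[str, GroupValues]
    intercept: GroupValues
    provenance: str = ""
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        canon_values: dict[str, GroupValues] = {}
        for label, v in self.values.items():
            canon = canonical_label(label)
            if canon in canon_values and canon_values[canon] != GroupValues(*v):
                raise ValueError(f"duplicate label {label!r} with conflicting values")
            canon_values[canon] = GroupValues(*v)
            if canon != label.strip():
                self.aliases[label.strip()] = canon
        self.values = canon_values
        self.intercept = GroupValues(*self.intercept)

    def resolve(self, label: str) -> Optional[str]:
        canon = canonical_label(label)
        if canon in self.values:
            return canon
        return self.aliases.get(label.strip()) or self.aliases.get(canon)

    def __contains__(self, label: str) -> bool:
        return self.resolve(label) is not None

    def lookup(self, label: str) -> GroupValues:
        canon = self.resolve(label)
        if canon is None:
            raise KeyError(f"group label {label!r} not in parameter table")
        return self.values[canon]

    @property
    def labels(self) -> list[str]:
        return sorted(self.values)

    def to_dict(self) -> dict:
        return {
            "groups": {
                label: {"S": v.S, "dfS": v.dfS, "dfG": v.dfG}
                for label, v in self.values.items()
            },
            "intercept": {
                "S": self.intercept.S,
                "dfS": self.intercept.dfS,
                "dfG": self.intercept.dfG,
            },
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GavParameterTable":
        groups = d.get("groups")
        if not isinstance(groups, Mapping):
            raise ValueError("parameter table needs a 'groups' mapping")
        inter = d.get("intercept")
        if not isinstance(inter, Mapping):
            raise ValueError("parameter table needs an 'intercept' mapping")

        def triple(label, m):
            try:
                return GroupValues(float(m["S"]), float(m["dfS"]), float(m["dfG"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"row {label!r} must give numeric S, dfS, dfG") from exc

        return cls(
            values={lab: triple(lab, v) for lab, v in groups.items()},
            intercept=triple("intercept", inter),
            provenance=str(d.get("provenance", "")),
        )


def estimate(
    gv: GroupVector, table: GavParameterTable, property: str
) -> float:
    """Group-additivity property estimate: intercept + sum of increments.

    ``property`` is one of ``"S"``, ``"dfS"`` (J mol^-1 K^-1) or ``"dfG"``
    (kJ mol^-1). Correction-term counts contribute like ordinary groups.
    Unknown labels raise a single KeyError naming every missing label.
    """
    if property not in PROPERTIES:
        raise ValueError(f"property must be one of {PROPERTIES}, got {property!r}")
    merged = gv.all_counts()
    missing = sorted(lab for lab in merged if lab not in table)
    if missing:
        raise KeyError(f"labels missing from parameter table: {missing}")
    idx = PROPERTIES.index(property)
    total = table.intercept[idx]
    for label, n in merged.items():
        total += n * table.lookup(label)[idx]
    return total


# ---------------------------------------------------------------------------
# atom bookkeeping

_CENTER_ATOMS = {
    "C": {"C": 1},
    "C_B": {"C": 1},
    "C_D": {"C": 1},
    "CO": {"C": 1, "O": 1},  # carbonyl O belongs to its CO center
    "O": {"O": 1},
    "N": {"N": 1},
}

# table rows outside the label grammar, with hand-assigned contributions
_SPECIAL_ATOMS = {
    "CH3(qua)": {"C": 1, "H": 3},
    "C_B-(NO2)(C_B)2": {"C": 1, "N": 1, "O": 2},  # nitro absorbed into its C_B
}


@dataclass(frozen=True)
class GroupAtomMap:
    """Per-group elemental contributions for atom-conservation checks."""

    contributions: Mapping[str, ElementalFormula]

    def __getitem__(self, label: str) -> ElementalFormula:
        canon = canonical_label(label)
        try:
            return self.contributions[canon]
        except KeyError:
            raise KeyError(f"no atom-map entry for group {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return canonical_label(label) in self.contributions


def derive_atom_contribution(label: str) -> ElementalFormula:
    """Atoms a single group contributes: its center (plus carbonyl O for CO),
    its H ligands, and nothing for correction terms."""
    canon = canonical_label(label)
    if canon in CORRECTION_LABELS:
        return ElementalFormula({})
    if canon in _SPECIAL_ATOMS:
        return ElementalFormula(dict(_SPECIAL_ATOMS[canon]))
    parsed = _parse_group_label(canon)
    if parsed is None:
        raise KeyError(f"cannot derive atoms for non-grammar label {label!r}")
    center, ligands = parsed
    atoms = dict(_CENTER_ATOMS[center])
    h = ligands.get("H", 0)
    if h:
        atoms["H"] = atoms.get("H", 0) + h
    return ElementalFormula(atoms)


def default_atom_map(labels) -> GroupAtomMap:
    return GroupAtomMap(
        {canonical_label(lab): derive_atom_contribution(lab) for lab in labels}
    )


def formula_from_groups(
    gv: GroupVector, atom_map: Optional[GroupAtomMap] = None
) -> ElementalFormula:
    """Elemental formula implied by a group vector (corrections add nothing).

    Without an explicit ``atom_map`` the contribution of each group is
    derived from its canonical label.
    """
    total = ElementalFormula({})
    for label, n in gv.counts.items():
        contrib = atom_map[label] if atom_map is not None else derive_atom_contribution(label)
        if n != int(n):
            raise ValueError(f"non-integer count {n} for {label!r} in formula derivation")
        total = total + contrib.scaled(int(n))
    return total


# ---------------------------------------------------------------------------
# table IO

_BUILTIN_RESOURCE = "benson_gav_mlr.json"
_builtin_cache: Optional[GavParameterTable] = None


def builtin_table() -> GavParameterTable:
    """The packaged MLR-refit Benson group values (acids and cyclic imides).

    Rows are stored exactly as published, including the aliased rows that
    share identical value triples (a likely artifact of collinearity in the
    original fit) and the four "radical" rows, which are loadable but never
    auto-assigned by perception.
    """
    global _builtin_cache
    if _builtin_cache is None:
        with resources.files("thermogav.data").joinpath(_BUILTIN_RESOURCE).open() as fh:
            _builtin_cache = GavParameterTable.from_dict(json.load(fh))
    return _builtin_cache


def load_table(source) -> GavParameterTable:
    """Load a parameter table from a JSON file path or file object."""
    if hasattr(source, "read"):
        return GavParameterTable.from_dict(json.load(source))
    with open(Path(source)) as fh:
        return GavParameterTable.from_dict(json.load(fh))


def save_table(table: GavParameterTable, path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(table.to_dict(), fh, indent=2)
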