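"""Elemental formulas, physical constants and element reference entropies.

The entropy of formation of a gas-phase species C_m H_n O_p N_o is obtained
by Hess's law from the formation reaction

    m C(s) + n/2 H2(g) + p/2 O2(g) + o/2 N2(g) -> CmHnOpNo(g)

so the only constants this package needs are the gas constant, the reference
temperature and the third-law absolute entropies of the elements in their
standard states (graphite and the diatomic gases).
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ElementalFormula",
    "Constants",
    "DEFAULT_CONSTANTS",
    "parse_formula",
    "element_entropy_sum",
]

#: CODATA 2018 molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618

#: Standard reference temperature, K.
T_REF = 298.15

# Reference species per element and the stoichiometric factor converting one
# atom of the element into moles of the reference species (1 for graphite,
# 1/2 for the diatomic gases).
_REFERENCE_SPECIES = {
    "C": ("C(s)", 1.0),
    "H": ("H2(g)", 0.5),
    "O": ("O2(g)", 0.5),
    "N": ("N2(g)", 0.5),
}

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map for a neutral closed-shell molecule.

    Counts are nonnegative integers; zero-count entries are dropped so two
    formulas compare equal iff they denote the same composition.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            if not isinstance(n, int) or isinstance(n, bool):
                raise TypeError(f"count for {el!r} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", dict(clean))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self):
        return iter(self.counts.items())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return ElementalFormula(dict(merged))

    def scaled(self, k: int) -> "ElementalFormula":
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    def to_string(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = sorted(
            self.counts,
            key=lambda el: (0, "") if el == "C" else (1, "") if el == "H" else (2, el),
        )
        return "".join(f"{el}{self.counts[el] if self.counts[el] != 1 else ''}" for el in order)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string() or "(empty)"


def parse_formula(text: str) -> ElementalFormula:
    """Parse a plain formula string like ``"C25H12N2O10"``.

    Element symbols each followed by an optional positive integer; no
    parentheses, charges, hydrates or isotopes. Repeated symbols accumulate.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: Counter = Counter()
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        symbol, digits = m.group(1), m.group(2)
        n = int(digits) if digits else 1
        if n == 0:
            raise ValueError(f"zero count for element {symbol!r} in {text!r}")
        counts[symbol] += n
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula(dict(counts))


@dataclass(frozen=True)
class Constants:
    """Physical constants and element reference entropies.

    ``element_entropies`` maps an element symbol to ``(S, u)``: the absolute
    entropy of its reference species (per mole of C(s), H2(g), O2(g), N2(g))
    and its standard uncertainty, both in J mol^-1 K^-1.
    """

    R: float = R_GAS
    T_ref: float = T_REF
    element_entropies: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "C": (5.74, 0.10),
            "H": (130.571, 0.003),
            "O": (205.043, 0.005),
            "N": (191.500, 0.004),
        }
    )

    def __post_init__(self):
        if self.R <= 0 or self.T_ref <= 0:
            raise ValueError("R and T_ref must be positive")
        for el, (s, u) in self.element_entropies.items():
            if s <= 0:
                raise ValueError(f"nonpositive reference entropy for {el}: {s}")
            if u < 0:
                raise ValueError(f"negative uncertainty for {el}: {u}")

    def reference_entropy(self, element: str) -> float:
        try:
            return self.element_entropies[element][0]
        except KeyError:
            raise KeyError(
                f"no reference-entropy entry for element {element!r}; "
                f"known: {sorted(self.element_entropies)}"
            ) from None

    @classmethod
    def from_dict(cls, d: Mapping) -> "Constants":
        """Build from a config block ``{R, T_ref, element_entropies}``.

        ``element_entropies`` values may be scalars (uncertainty 0) or
        ``[S, u]`` pairs. Omitted keys fall back to the defaults.
        """
        base = cls()
        entropies = dict(base.element_entropies)
        for el, v in (d.get("element_entropies") or {}).items():
            if isinstance(v, (int, float)):
                entropies[el] = (float(v), 0.0)
            else:
                s, u = v
                entropies[el] = (float(s), float(u))
        return cls(
            R=float(d.get("R", base.R)),
            T_ref=float(d.get("T_ref", base.T_ref)),
            element_entropies=entropies,
        )

    @classmethod
    def from_json(cls, path) -> "Constants":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


DEFAULT_CONSTANTS = Constants()


def element_entropy_sum(
    formula: ElementalFormula, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Absolute entropy of the stoichiometric elements, J mol^-1 K^-1.

    For C_m H_n O_p N_o this is m*S(C,s) + n/2*S(H2,g) + p/2*S(O2,g)
    + o/2*S(N2,g) — the elemental side of the formation reaction. Additive
    over formulas; zero for the empty formula.
    """
    total = 0.0
    for el, n in formula:
        if el not in _REFERENCE_SPECIES:
            # still allow user-extended constants tables
            if el not in constants.element_entropies:
                raise KeyError(
                    f"no reference-entropy entry for element {el!r}"
                )
            factor = 0.5  # assume diatomic reference for extensions
        else:
            factor = _REFERENCE_SPECIES[el][1]
        total += n * factor * constants.reference_entropy(el)
    return total


def element_entropy_uncertainty(
    formula: ElementalFormula, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Root-sum-square uncertainty of :func:`element_entropy_sum` (opt-in)."""
    acc = 0.0
    for el, n in formula:
        factor = _REFERENCE_SPECIES.get(el, (None, 0.5))[1]
        u = constants.element_entropies[el][1]
        acc += (n * factor * u) ** 2
    return acc ** 0.5


def _merge(formulas: Iterable[ElementalFormula]) -> ElementalFormula:
    out = ElementalFormula({})
    for f in formulas:
        out = out + f
    return out
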