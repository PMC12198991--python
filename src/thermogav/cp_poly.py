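"""Cubic gas-phase heat-capacity polynomials.

Cp(T) = a3·T³ + a2·T² + a1·T + a0 with Cp in J mol^-1 K^-1 and T in K.
The packaged coefficient sets cover the two diaminobenzoic acids and the
two diimidetricarboxylic acids over 298.15-613.15 K (the DSC scan range,
a packaging convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = ["CpPolynomial", "evaluate", "fit_cubic", "packaged_cp", "packaged_cp_names"]


@dataclass(frozen=True)
class CpPolynomial:
    """Cubic Cp model; coefficients in descending power order a3..a0."""

    a3: float
    a2: float
    a1: float
    a0: float
    valid_range: tuple[float, float] = (298.15, 613.15)
    label: str = ""

    def __post_init__(self):
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError(f"empty validity range {self.valid_range}")

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.a3, self.a2, self.a1, self.a0)

    def __call__(self, T: float) -> float:
        return evaluate(self, T)

    def to_dict(self) -> dict:
        return {
            "a3": self.a3, "a2": self.a2, "a1": self.a1, "a0": self.a0,
            "T_min": self.valid_range[0], "T_max": self.valid_range[1],
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d) -> "CpPolynomial":
        return cls(
            a3=float(d["a3"]), a2=float(d["a2"]), a1=float(d["a1"]), a0=float(d["a0"]),
            valid_range=(float(d.get("T_min", 298.15)), float(d.get("T_max", 613.15))),
            label=str(d.get("label", "")),
        )


def evaluate(p: CpPolynomial, T: float) -> float:
    """Polynomial Cp at T (K); warns outside the validity range."""
    lo, hi = p.valid_range
    if not lo <= T <= hi:
        warnings.warn(
            f"T={T} K outside validity range [{lo}, {hi}] of {p.label or 'polynomial'}",
            stacklevel=2,
        )
    return ((p.a3 * T + p.a2) * T + p.a1) * T + p.a0


def fit_cubic(samples: Sequence[tuple[float, float]]) -> tuple[CpPolynomial, float]:
    """Least-squares cubic through (T, Cp) samples; returns (model, R²).

    Needs at least four samples with distinct temperatures.
    """
    pts = list(samples)
    if len(pts) < 4:
        raise ValueError(f"need >= 4 samples for a cubic fit, got {len(pts)}")
    T = np.asarray([t for t, _ in pts], dtype=float)
    y = np.asarray([c for _, c in pts], dtype=float)
    if len(np.unique(T)) < 4:
        raise ValueError("need >= 4 distinct temperatures for a cubic fit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coeffs = np.polyfit(T, y, deg=3)
    pred = np.polyval(coeffs, T)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    poly = CpPolynomial(
        *(float(c) for c in coeffs),
        valid_range=(float(T.min()), float(T.max())) if T.min() < T.max() else (float(T.min()), float(T.min()) + 1),
        label="fit",
    )
    return poly, r2


_RESOURCE = "cp_polynomials.json"


def packaged_cp_names() -> list[str]:
    with resources.files("thermogav.data").joinpath(_RESOURCE).open() as fh:
        return sorted(json.load(fh))


def packaged_cp(name: str, reading: str = "as_printed") -> CpPolynomial:
    """Load a packaged Cp polynomial by compound name.

    The two DITA sets carry an ambiguously printed quadratic coefficient
    ("0.0014e-4"); ``reading="as_printed"`` (default) uses the literal value
    −1.4e−7 with a warning, ``reading="alternative"`` uses the annotated
    alternative interpretation −1.4e−3.
    """
    if reading not in ("as_printed", "alternative"):
        raise ValueError("reading must be 'as_printed' or 'alternative'")
    with resources.files("thermogav.data").joinpath(_RESOURCE).open() as fh:
        data = json.load(fh)
    if name not in data:
        raise KeyError(f"no packaged Cp polynomial for {name!r}; know {sorted(data)}")
    d = dict(data[name])
    if "a2_alternative" in d:
        if reading == "alternative":
            d["a2"] = d["a2_alternative"]
        else:
            warnings.warn(
                f"{name}: quadratic Cp coefficient is ambiguous in the source "
                f"({d['a2']} as printed vs {d['a2_alternative']} alternative); "
                "using the printed value",
                stacklevel=2,
            )
        d.pop("a2_alternative")
    d.setdefault("label", name)
    return CpPolynomial.from_dict(d)
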