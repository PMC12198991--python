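"""Decompose C/H/N/O molecular graphs into Benson group labels.

Each heavy atom becomes one group center — except a carbonyl oxygen, which
is absorbed into its carbonyl-carbon (CO) center — and the group label
records the center type plus the types of its bonded neighbors and its
hydrogen count. Center typing:

* ``CO``  carbon double-bonded to an oxygen,
* ``C_B`` aromatic carbon,
* ``C_D`` non-aromatic sp2 carbon,
* ``C``   sp3 carbon,
* ``O``/``N`` heteroatom centers.

A ring-strain correction (``rsc``) is emitted once per five-membered ring
containing the CO-N-CO imide motif. Aromatic ortho/meta/para substitution
corrections are a separate annotation pass so callers control whether they
are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .gav_model import GroupVector, _format_group_label

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "perceive_groups",
    "annotate_substitution_corrections",
    "from_smiles",
]

_SUPPORTED_ELEMENTS = {"C", "H", "N", "O"}
_STANDARD_VALENCE = {"C": 4, "N": 3, "O": 2}
AROMATIC = "ar"


@dataclass(frozen=True)
class Atom:
    element: str
    h_count: int = 0
    aromatic: bool = False


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: object = 1  # 1, 2, 3 or "ar"


@dataclass
class MolecularGraph:
    """Heavy-atom graph with implicit hydrogens.

    ``atoms`` is a list of :class:`Atom`; ``bonds`` reference atom indices.
    Aromaticity is taken from the input flags (typically set by the SMILES
    reader); no independent aromaticity perception is done.
    """

    atoms: list[Atom]
    bonds: list[Bond]

    def __post_init__(self):
        n = len(self.atoms)
        for a in self.atoms:
            if a.element not in _SUPPORTED_ELEMENTS - {"H"}:
                raise ValueError(f"unsupported element {a.element!r} (C/N/O heavy atoms only)")
            if a.h_count < 0:
                raise ValueError("negative hydrogen count")
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"bad bond ({b.i}, {b.j})")
            key = frozenset((b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond ({b.i}, {b.j})")
            seen.add(key)
            if b.order not in (1, 2, 3, AROMATIC):
                raise ValueError(f"bad bond order {b.order!r}")
        self._validate_valence()

    # -- helpers -----------------------------------------------------------

    def neighbors(self, idx: int) -> list[tuple[int, object]]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append((b.j, b.order))
            elif b.j == idx:
                out.append((b.i, b.order))
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def formula_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
            if a.h_count:
                counts["H"] = counts.get("H", 0) + a.h_count
        return counts

    def rings(self, max_size: int = 6) -> list[list[int]]:
        """All simple rings up to ``max_size`` atoms, as ordered atom lists."""
        g = self.to_networkx()
        seen: set[frozenset] = set()
        out = []
        for cyc in nx.simple_cycles(g, length_bound=max_size):
            key = frozenset(cyc)
            if len(key) == len(cyc) and key not in seen:
                seen.add(key)
                out.append(list(cyc))
        return out

    def _validate_valence(self):
        for idx, atom in enumerate(self.atoms):
            nbrs = self.neighbors(idx)
            val = _STANDARD_VALENCE[atom.element]
            if atom.aromatic:
                # aromatic bond orders are fractional; check degree bounds only
                if atom.h_count + len(nbrs) > val:
                    raise ValueError(
                        f"atom {idx} ({atom.element}): degree {len(nbrs)} + "
                        f"{atom.h_count} H exceeds valence {val}"
                    )
                if not any(o == AROMATIC for _, o in nbrs):
                    raise ValueError(f"atom {idx} flagged aromatic but has no aromatic bond")
            else:
                if any(o == AROMATIC for _, o in nbrs):
                    raise ValueError(f"atom {idx} has an aromatic bond but no aromatic flag")
                total = sum({1: 1, 2: 2, 3: 3}[o] for _, o in nbrs) + atom.h_count
                if total != val:
                    raise ValueError(
                        f"atom {idx} ({atom.element}): bond-order sum {total} != valence {val}"
                    )

    # -- IO ----------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "atoms": [
                {"element": a.element, "h_count": a.h_count, "aromatic": a.aromatic}
                for a in self.atoms
            ],
            "bonds": [{"i": b.i, "j": b.j, "order": b.order} for b in self.bonds],
        }

    @classmethod
    def from_dict(cls, d) -> "MolecularGraph":
        atoms = [
            Atom(a["element"], int(a.get("h_count", 0)), bool(a.get("aromatic", False)))
            for a in d["atoms"]
        ]
        bonds = [Bond(int(b["i"]), int(b["j"]), b.get("order", 1)) for b in d["bonds"]]
        return cls(atoms, bonds)


def from_smiles(smiles: str) -> MolecularGraph:
    """Build a :class:`MolecularGraph` from SMILES via RDKit."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    if any(a.GetFormalCharge() != 0 or a.GetNumRadicalElectrons() != 0 for a in mol.GetAtoms()):
        raise ValueError("charged or radical species are not supported")
    atoms = [
        Atom(a.GetSymbol(), a.GetTotalNumHs(), a.GetIsAromatic()) for a in mol.GetAtoms()
    ]
    order_map = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
        Chem.BondType.AROMATIC: AROMATIC,
    }
    bonds = []
    for b in mol.GetBonds():
        try:
            order = order_map[b.GetBondType()]
        except KeyError:
            raise ValueError(f"unsupported bond type {b.GetBondType()}") from None
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms, bonds)


# ---------------------------------------------------------------------------
# perception


def _center_types(mol: MolecularGraph) -> tuple[list[Optional[str]], set[int]]:
    """Type each heavy atom; return (types, absorbed carbonyl-O indices)."""
    types: list[Optional[str]] = [None] * len(mol.atoms)
    absorbed: set[int] = set()
    # carbonyl detection first: C=O pairs
    for b in mol.bonds:
        if b.order != 2:
            continue
        pair = {mol.atoms[b.i].element, mol.atoms[b.j].element}
        if pair == {"C", "O"}:
            c_idx, o_idx = (b.i, b.j) if mol.atoms[b.i].element == "C" else (b.j, b.i)
            types[c_idx] = "CO"
            absorbed.add(o_idx)
    for idx, atom in enumerate(mol.atoms):
        if types[idx] == "CO" or idx in absorbed:
            continue
        nbr_orders = [o for _, o in mol.neighbors(idx)]
        if atom.element == "C":
            if any(o == 3 for o in nbr_orders):
                raise ValueError(f"atom {idx}: triple-bonded carbon has no Benson label here")
            if atom.aromatic:
                types[idx] = "C_B"
            elif any(o == 2 for o in nbr_orders):
                types[idx] = "C_D"
            else:
                types[idx] = "C"
        elif atom.element == "O":
            types[idx] = "O"
        elif atom.element == "N":
            types[idx] = "N"
    return types, absorbed


def _imide_ring_count(mol: MolecularGraph, types: Sequence[Optional[str]]) -> int:
    """Five-membered rings containing the CO-N-CO motif (imide rings)."""
    count = 0
    for ring in mol.rings(max_size=5):
        if len(ring) != 5:
            continue
        ring_set = set(ring)
        for idx in ring:
            if types[idx] != "N":
                continue
            co_in_ring = sum(
                1 for j, _ in mol.neighbors(idx) if j in ring_set and types[j] == "CO"
            )
            if co_in_ring == 2:
                count += 1
                break
    return count


def perceive_groups(mol: MolecularGraph) -> GroupVector:
    """Benson group vector of a molecule: one group per center atom plus
    ``rsc`` once per five-membered imide ring.

    The result's implied formula equals the molecule's formula (carbonyl
    oxygens are carried by their CO centers, hydrogens by their heavy atom).
    """
    types, absorbed = _center_types(mol)
    counts: dict[str, float] = {}
    for idx, atom in enumerate(mol.atoms):
        if idx in absorbed:
            continue
        center = types[idx]
        ligands: dict[str, int] = {}
        for j, order in mol.neighbors(idx):
            if j in absorbed:
                continue  # the CO center's own carbonyl oxygen
            t = types[j]
            ligands[t] = ligands.get(t, 0) + 1
        if atom.h_count:
            ligands["H"] = atom.h_count
        if not ligands:
            raise ValueError(
                f"atom {idx} ({atom.element}) has no ligands; single-heavy-atom "
                "species have no Benson decomposition"
            )
        label = _format_group_label(center, ligands)
        counts[label] = counts.get(label, 0) + 1
    n_rsc = _imide_ring_count(mol, types)
    if n_rsc:
        counts["rsc"] = n_rsc
    return GroupVector(counts)


def _aromatic_six_rings(mol: MolecularGraph) -> Iterable[list[int]]:
    for ring in mol.rings(max_size=6):
        if len(ring) == 6 and all(mol.atoms[i].aromatic for i in ring):
            yield ring


def annotate_substitution_corrections(mol: MolecularGraph, gv: GroupVector) -> GroupVector:
    """Add ortho/meta/para substitution corrections for aromatic six-rings.

    Every unordered pair of substituted ring positions contributes one
    correction, classified by ring distance (1 -> o-, 2 -> m-, 3 -> p-).
    A position counts as substituted when it has a heavy-atom neighbor
    outside the ring (fused-ring attachments included).
    """
    extra: dict[str, int] = {}
    for ring in _aromatic_six_rings(mol):
        ring_set = set(ring)
        substituted = [
            pos
            for pos, idx in enumerate(ring)
            if any(j not in ring_set for j, _ in mol.neighbors(idx))
        ]
        for a in range(len(substituted)):
            for b in range(a + 1, len(substituted)):
                d = abs(substituted[a] - substituted[b])
                d = min(d, 6 - d)
                label = {1: "correction o-", 2: "correction m-", 3: "correction p-"}[d]
                extra[label] = extra.get(label, 0) + 1
    if not extra:
        return gv
    return gv + GroupVector(extra)
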