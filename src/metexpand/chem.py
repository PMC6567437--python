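"""Molecular structures as atom-typed graphs.

Molecules are represented as lightweight graphs of :class:`TypedAtom` nodes
with explicit bond orders.  RDKit does the heavy lifting for parsing,
aromaticity perception, valence checking and canonicalisation; the graph
layer exists so that reaction-rule extraction and application can perform
controlled local edits and re-derive hydrogen counts afterwards.

Conventions
-----------
* Hydrogens are implicit everywhere; explicit-H input is collapsed on parse.
* Stereochemistry is ignored throughout (canonical keys are constitutional).
* Aromatic rings are stored with aromatic bond order; Kekulé input is
  normalised by RDKit's sanitisation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping

from rdkit import Chem
from rdkit import RDLogger

from .atom_types import type_atom

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ChemError",
    "ParseError",
    "ValenceError",
    "TypedAtom",
    "Bond",
    "MolecularGraph",
    "ElementFormula",
    "parse_structure",
    "assign_atom_types",
    "canonical_key",
    "formula_of",
    "from_rdkit",
]

# bond orders are stored as short string codes
SINGLE, DOUBLE, TRIPLE, AROMATIC = "1", "2", "3", "ar"

_RD_ORDER = {
    SINGLE: Chem.BondType.SINGLE,
    DOUBLE: Chem.BondType.DOUBLE,
    TRIPLE: Chem.BondType.TRIPLE,
    AROMATIC: Chem.BondType.AROMATIC,
}
_FROM_RD_ORDER = {v: k for k, v in _RD_ORDER.items()}


class ChemError(ValueError):
    """Base error for structure handling."""


class ParseError(ChemError):
    pass


class ValenceError(ChemError):
    pass


@dataclass(frozen=True)
class TypedAtom:
    index: int
    element: str
    implicit_h: int
    formal_charge: int = 0
    aromatic: bool = False
    atom_type: str | None = None


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: str  # one of "1", "2", "3", "ar"

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i


@dataclass
class MolecularGraph:
    """An atom-typed molecular graph with implicit hydrogens.

    Treated as immutable; edits construct new graphs.
    """

    atoms: tuple[TypedAtom, ...]
    bonds: tuple[Bond, ...]
    _adj: dict[int, list[tuple[int, str]]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[frozenset[int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ChemError(f"bond ({b.i},{b.j}) references invalid atom index")
            if b.i == b.j:
                raise ChemError(f"self-bond on atom {b.i}")
            key = frozenset((b.i, b.j))
            if key in seen:
                raise ChemError(f"duplicate bond ({b.i},{b.j})")
            seen.add(key)

    # -- graph access -------------------------------------------------
    def neighbors(self, idx: int) -> list[tuple[int, str]]:
        """Neighbour atom indices of ``idx`` with the connecting bond order."""
        if self._adj is None:
            adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(len(self.atoms))}
            for b in self.bonds:
                adj[b.i].append((b.j, b.order))
                adj[b.j].append((b.i, b.order))
            self._adj = adj
        return self._adj[idx]

    def degree(self, idx: int) -> int:
        return len(self.neighbors(idx))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def connected_components(self) -> list[set[int]]:
        unseen = set(range(self.n_atoms))
        comps = []
        while unseen:
            stack = [unseen.pop()]
            comp = set(stack)
            while stack:
                cur = stack.pop()
                for nb, _ in self.neighbors(cur):
                    if nb in unseen:
                        unseen.discard(nb)
                        comp.add(nb)
                        stack.append(nb)
            comps.append(comp)
        return comps

    # -- RDKit bridge -------------------------------------------------
    def to_rdkit(self, recompute_h: bool = False) -> Chem.Mol:
        """Convert to a sanitised RDKit molecule.

        With ``recompute_h=True`` the stored implicit-hydrogen counts are
        discarded and re-derived from default valences — used after graph
        edits to rebalance hydrogens.  Raises :class:`ValenceError` when the
        resulting molecule is chemically invalid.
        """
        rw = Chem.RWMol()
        for a in self.atoms:
            ra = Chem.Atom(a.element)
            ra.SetFormalCharge(a.formal_charge)
            ra.SetIsAromatic(a.aromatic)
            if not recompute_h:
                ra.SetNumExplicitHs(a.implicit_h)
                ra.SetNoImplicit(True)
            rw.AddAtom(ra)
        for b in self.bonds:
            rw.AddBond(b.i, b.j, _RD_ORDER[b.order])
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # rdkit raises several exception types
            raise ValenceError(f"invalid molecule: {exc}") from exc
        return mol


def from_rdkit(mol: Chem.Mol) -> MolecularGraph:
    """Build a typed graph from a sanitised RDKit molecule."""
    mol = Chem.RemoveHs(mol)
    atoms = tuple(
        TypedAtom(
            index=a.GetIdx(),
            element=a.GetSymbol(),
            implicit_h=a.GetTotalNumHs(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _FROM_RD_ORDER[b.GetBondType()])
        for b in mol.GetBonds()
    )
    return assign_atom_types(MolecularGraph(atoms, bonds))


def parse_structure(text: str, format: str = "smiles") -> MolecularGraph:
    """Parse a SMILES string or an MDL molfile (V2000) into a typed graph.

    Hydrogens are normalised to implicit counts and aromaticity is
    perceived.  Raises :class:`ParseError` on unreadable input and
    :class:`ValenceError` on valence violations (naming the atom).
    """
    if format not in ("smiles", "molfile"):
        raise ValueError(f"unknown structure format: {format!r}")
    if format == "smiles":
        mol = Chem.MolFromSmiles(text, sanitize=False)
    else:
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if mol is None:
        raise ParseError(f"unparsable {format} input")
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException as exc:
        m = re.search(r"# (\d+)", str(exc))
        at = f" at atom {m.group(1)}" if m else ""
        raise ValenceError(f"valence violation{at}: {exc}") from exc
    except Exception as exc:
        raise ParseError(f"cannot sanitise {format} input: {exc}") from exc
    return from_rdkit(mol)


def assign_atom_types(g: MolecularGraph) -> MolecularGraph:
    """Label every atom with a radius-1 environment type code.

    The type is a pure function of the atom's element, formal charge,
    aromatic flag, implicit hydrogen count and the multiset of
    (bond order, neighbour element) pairs — nothing beyond the first
    shell.  See :mod:`metexpand.atom_types` for the code table.
    """
    typed = []
    for a in g.atoms:
        nbrs = [(order, g.atoms[j].element) for j, order in g.neighbors(a.index)]
        code = type_atom(a.element, a.formal_charge, a.aromatic, a.implicit_h, nbrs)
        typed.append(replace(a, atom_type=code))
    return MolecularGraph(tuple(typed), g.bonds)


def canonical_key(g: MolecularGraph) -> str:
    """Order-invariant constitutional identity key (canonical SMILES).

    Two graphs receive the same key iff they share constitution and bond
    orders; stereochemistry is never stored, hence never compared.
    """
    smi = Chem.MolToSmiles(g.to_rdkit())
    norm = Chem.MolFromSmiles(smi)
    return Chem.MolToSmiles(norm) if norm is not None else smi


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementFormula:
    """Element → count map (hydrogen counted separately) plus net charge."""

    counts: Mapping[str, int]
    charge: int = 0

    @classmethod
    def from_string(cls, formula: str, charge: int = 0) -> "ElementFormula":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"bad formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"bad formula {formula!r}")
        return cls(counts, charge)

    def heavy(self) -> dict[str, int]:
        return {el: n for el, n in self.counts.items() if el != "H" and n}

    def __add__(self, other: "ElementFormula") -> "ElementFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementFormula(counts, self.charge + other.charge)

    def scaled(self, k: float) -> "ElementFormula":
        return ElementFormula(
            {el: k * n for el, n in self.counts.items()}, k * self.charge
        )

    def to_string(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        items = {el: n for el, n in self.counts.items() if n}
        parts = []
        for el in ("C", "H"):
            if el in items:
                parts.append(f"{el}{_fmt(items.pop(el))}")
        parts.extend(f"{el}{_fmt(items[el])}" for el in sorted(items))
        return "".join(parts)


def _fmt(n: int) -> str:
    return "" if n == 1 else str(int(n) if float(n).is_integer() else n)


def formula_of(g: MolecularGraph) -> ElementFormula:
    counts: dict[str, int] = {}
    charge = 0
    for a in g.atoms:
        counts[a.element] = counts.get(a.element, 0) + 1
        if a.implicit_h:
            counts["H"] = counts.get("H", 0) + a.implicit_h
        charge += a.formal_charge
    return ElementFormula(counts, charge)
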