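"""Radius-1 atom environment typing.

Atoms are labelled with short environment codes in the spirit of the KEGG
atom-type vocabulary used by reaction-rule (RDM/RCLASS-style) methods: an
element class refined by the immediate bonding environment, e.g. a carbonyl
carbon is distinguished from a carbinol carbon, a phosphate phosphorus from
a phosphine phosphorus.  The scheme here is self-contained and documented
in ``data/atom_types.tsv`` (the versioned vocabulary); it is intentionally
coarse — reaction-rule keys only need consistent, discriminating local
labels.

The code assigned to an atom is a pure function of

* its element symbol,
* its formal charge (appended as a ``+``/``-`` suffix),
* its aromatic flag,
* its implicit hydrogen count, and
* the multiset of (bond order, neighbour element) pairs.

Nothing beyond the first shell is consulted, so retyping after a remote
(distance > 1) modification leaves an atom's code unchanged.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Sequence

__all__ = ["type_atom", "atom_type_table", "element_class"]

_HALOGENS = {"F", "Cl", "Br", "I"}
_SUPPORTED = {"C", "N", "O", "S", "P", "H"} | _HALOGENS


def element_class(code: str) -> str:
    """Element symbol encoded in an atom-type code (e.g. ``C.co`` → ``C``)."""
    base = code.rstrip("+-")
    if base.startswith("X"):
        return base[1:]
    return base.split(".", 1)[0]


def _count(nbrs: Sequence[tuple[str, str]], order: str | None = None,
           element: str | None = None) -> int:
    n = 0
    for o, el in nbrs:
        if (order is None or o == order) and (element is None or el == element):
            n += 1
    return n


def _base_type(element: str, aromatic: bool, implicit_h: int,
               nbrs: Sequence[tuple[str, str]]) -> str:
    heavy_deg = len(nbrs)
    if element == "C":
        if aromatic:
            return "C.ar"
        if _count(nbrs, "3", "N"):
            return "C.nit"
        if _count(nbrs, "2", "O") >= 2:
            return "C.oo2"
        if _count(nbrs, "2", "O") and (_count(nbrs, "1", "O")):
            return "C.coo"
        if _count(nbrs, "2", "O") and _count(nbrs, "1", "N"):
            return "C.con"
        if _count(nbrs, "2", "O"):
            return "C.co"
        if _count(nbrs, "2", "N"):
            return "C.imn"
        if _count(nbrs, "3", "C"):
            return "C.yne"
        if _count(nbrs, "2", "C"):
            return "C.ene"
        k = min(3, sum(1 for o, el in nbrs if o == "1" and el not in ("C", "H")))
        return f"C.h{k}"
    if element == "N":
        if aromatic:
            return "N.ar"
        if _count(nbrs, "2", "O"):
            return "N.oxo"
        if _count(nbrs, "3"):
            return "N.nit"
        if _count(nbrs, "2"):
            return "N.d"
        return {0: "N.0", 1: "N.p", 2: "N.s", 3: "N.t"}.get(heavy_deg, "N.q")
    if element == "O":
        if aromatic:
            return "O.ar"
        if _count(nbrs, "2"):
            if _count(nbrs, "2", "P"):
                return "O.dp"
            if _count(nbrs, "2", "S"):
                return "O.ds"
            return "O.dc"
        if heavy_deg >= 2:
            return "O.ep" if _count(nbrs, element="P") else "O.ee"
        if heavy_deg == 1:
            if _count(nbrs, element="P"):
                return "O.p1"
            return "O.h" if implicit_h else "O.t"
        return "O.w"
    if element == "S":
        if aromatic:
            return "S.ar"
        if _count(nbrs, "2"):
            return "S.d"
        if heavy_deg >= 2:
            return "S.e"
        if heavy_deg == 1:
            return "S.h" if implicit_h else "S.t"
        return "S.0"
    if element == "P":
        n_o = _count(nbrs, element="O")
        if n_o >= 3:
            return "P.o"
        if n_o:
            return "P.o1"
        return "P.g"
    if element in _HALOGENS:
        return f"{element}.x"
    if element == "H":
        return "H"
    # elements outside the supported set get a generic class
    return f"X{element}"


def type_atom(element: str, formal_charge: int, aromatic: bool,
              implicit_h: int, nbrs: Sequence[tuple[str, str]]) -> str:
    """Return the environment type code for one atom.

    ``nbrs`` is the multiset of (bond order, neighbour element) pairs of
    the atom's incident bonds; orders are the string codes used by
    :mod:`metexpand.chem` (``"1"``, ``"2"``, ``"3"``, ``"ar"``).
    """
    code = _base_type(element, aromatic, implicit_h, nbrs)
    if formal_charge > 0:
        code += "+"
    elif formal_charge < 0:
        code += "-"
    return code


def atom_type_table() -> dict[str, str]:
    """The versioned code → description vocabulary."""
    text = resources.files("metexpand.data").joinpath("atom_types.tsv").read_text()
    table = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        table[row[0]] = row[1]
    return table
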