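"""Reaction-rule extraction: RDM patterns and biotransformation operators.

For a reactant–product pair, the structural change is decomposed in the
RDM style used by reaction-rule methods: a Reaction Centre atom (R) that
exists on both sides and is the centre of the transformation, Difference
region atoms (D) adjacent to R that differ between the sides, and Matched
region atoms (M) adjacent to R that the transformation preserves.  Each
single-centre pair yields a lookup-table operator whose key is the (R, M)
environment in the substrate and whose value is the (R, D) payload in the
product, together with an explicit local graph edit that reproduces the
product when applied to the substrate at the originating site.

Pairs whose change decomposes into more than one reaction centre are
flagged multi-centre and excluded from operator generation; multi-centre
enzymes (e.g. transketolase) are out of scope.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from rdkit import Chem
from rdkit.Chem import rdFMCS

from . import chem
from .chem import MolecularGraph
from .model_io import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "AtomMapping",
    "RDMPattern",
    "FragmentSpec",
    "Rebond",
    "GraphEdit",
    "Provenance",
    "OperatorOrigin",
    "Operator",
    "OperatorTable",
    "map_atoms",
    "extract_rdm",
    "build_operator_table",
    "bundled_cofactor_keys",
]

_MAX_MATCHES = 200


# ---------------------------------------------------------------------------
# atom mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomMapping:
    """Partial injective substrate→product atom map from a connected MCS."""

    pairs: tuple[tuple[int, int], ...]
    lost: tuple[int, ...]    # substrate atoms without a partner
    gained: tuple[int, ...]  # product atoms without a partner

    @property
    def sub_to_prod(self) -> dict[int, int]:
        return dict(self.pairs)

    @property
    def prod_to_sub(self) -> dict[int, int]:
        return {j: i for i, j in self.pairs}

    def inverse(self) -> "AtomMapping":
        return AtomMapping(
            pairs=tuple(sorted((j, i) for i, j in self.pairs)),
            lost=self.gained,
            gained=self.lost,
        )

    @property
    def n_mapped(self) -> int:
        return len(self.pairs)


def _seed_mappings(substrate: MolecularGraph, product: MolecularGraph,
                   sub_mol: Chem.Mol, prod_mol: Chem.Mol):
    """Base pairings from MCS under two atom comparators: plain elements,
    and atom types (encoded as isotopes so FMCS can compare them)."""
    seeds = []

    def run(ms, mp, **kwargs):
        res = rdFMCS.FindMCS(
            [ms, mp], maximizeBonds=False,
            bondCompare=rdFMCS.BondCompare.CompareOrderExact, timeout=20,
            **kwargs,
        )
        if not res.numAtoms or not res.smartsString:
            return
        query = Chem.MolFromSmarts(res.smartsString)
        if query is None:
            return
        subs = ms.GetSubstructMatches(query, uniquify=False,
                                      maxMatches=_MAX_MATCHES)
        prods = mp.GetSubstructMatches(query, uniquify=False,
                                       maxMatches=_MAX_MATCHES)
        for s in subs[:40]:
            for p in prods[:40]:
                seeds.append(list(zip(s, p)))

    run(sub_mol, prod_mol)

    vocab: dict[str, int] = {}

    def isotope_mol(mol: Chem.Mol, graph: MolecularGraph) -> Chem.Mol:
        m = Chem.Mol(mol)
        for atom in m.GetAtoms():
            code = graph.atoms[atom.GetIdx()].atom_type or "?"
            atom.SetIsotope(vocab.setdefault(code, len(vocab) + 1))
        return m

    run(isotope_mol(sub_mol, substrate), isotope_mol(prod_mol, product),
        atomCompare=rdFMCS.AtomCompare.CompareIsotopes)
    return seeds


def _extend_greedy(substrate: MolecularGraph, product: MolecularGraph,
                   pairs: list[tuple[int, int]],
                   sub_ranks: list[int], prod_ranks: list[int]):
    """Grow a partial mapping over unmapped neighbours that agree on
    element and connecting bond order (deterministic under canonical
    ranks)."""
    mapped_s = {i for i, _ in pairs}
    mapped_p = {j for _, j in pairs}
    frontier = sorted(pairs, key=lambda ij: (sub_ranks[ij[0]], ij))
    while frontier:
        i, j = frontier.pop(0)
        sub_nb = sorted(
            ((a, o) for a, o in substrate.neighbors(i) if a not in mapped_s),
            key=lambda ao: (sub_ranks[ao[0]], ao[0]),
        )
        for a, o in sub_nb:
            if a in mapped_s:
                continue
            cands = [
                b for b, o2 in product.neighbors(j)
                if b not in mapped_p and o2 == o
                and product.atoms[b].element == substrate.atoms[a].element
            ]
            if not cands:
                continue
            b = min(cands, key=lambda x: (
                product.atoms[x].atom_type != substrate.atoms[a].atom_type,
                prod_ranks[x], x,
            ))
            pairs.append((a, b))
            mapped_s.add(a)
            mapped_p.add(b)
            frontier.append((a, b))
    return pairs


def map_atoms(substrate: MolecularGraph, product: MolecularGraph) -> AtomMapping:
    """Map substrate atoms onto product atoms by connected MCS search.

    Candidate mappings are generated from maximum-common-substructure
    searches (element-level and atom-type-level comparators), greedily
    extended over order-compatible neighbours, and ranked by: most mapped
    atoms, fewest connected change components, most atom-type-exact
    matches, lexicographically smallest pairing.  The result is
    deterministic for a given atom order.
    """
    sub_mol = substrate.to_rdkit()
    prod_mol = product.to_rdkit()
    sub_ranks = list(Chem.CanonicalRankAtoms(sub_mol, breakTies=True))
    prod_ranks = list(Chem.CanonicalRankAtoms(prod_mol, breakTies=True))

    candidates: list[tuple[tuple[int, int], ...]] = []
    seen: set[tuple] = set()
    for base in _seed_mappings(substrate, product, sub_mol, prod_mol):
        full = tuple(sorted(_extend_greedy(
            substrate, product, base, sub_ranks, prod_ranks)))
        if full not in seen:
            seen.add(full)
            candidates.append(full)

    if not candidates:
        # no common edge subgraph; fall back to a single best atom pair
        best = None
        for a in substrate.atoms:
            for b in product.atoms:
                if a.element != b.element:
                    continue
                score = (a.atom_type == b.atom_type, -a.index, -b.index)
                if best is None or score > best[0]:
                    best = (score, (a.index, b.index))
        if best is None:
            return AtomMapping((), tuple(range(substrate.n_atoms)),
                               tuple(range(product.n_atoms)))
        pair = best[1]
        return AtomMapping(
            (pair,),
            tuple(i for i in range(substrate.n_atoms) if i != pair[0]),
            tuple(j for j in range(product.n_atoms) if j != pair[1]),
        )

    def to_mapping(pairs) -> AtomMapping:
        mapped_s = {i for i, _ in pairs}
        mapped_p = {j for _, j in pairs}
        return AtomMapping(
            pairs=tuple(sorted(pairs)),
            lost=tuple(i for i in range(substrate.n_atoms) if i not in mapped_s),
            gained=tuple(j for j in range(product.n_atoms) if j not in mapped_p),
        )

    def score(pairs):
        mapping = to_mapping(pairs)
        n_comps = len(_change_components(substrate, product, mapping)[0]) \
            if mapping.pairs else 0
        exact = sum(
            1 for i, j in pairs
            if substrate.atoms[i].atom_type == product.atoms[j].atom_type
        )
        return (-len(pairs), n_comps, -exact, tuple(sorted(pairs)))

    return to_mapping(min(candidates, key=score))


# ---------------------------------------------------------------------------
# RDM decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentSpec:
    """A connected fragment hanging off the reaction centre.

    ``atoms`` are (element, formal charge, aromatic) triples in local
    numbering, ``bonds`` the fragment-internal bonds, and ``attach`` the
    (local atom, bond order) pairs that connect the fragment to R.
    """

    atoms: tuple[tuple[str, int, bool], ...]
    bonds: tuple[tuple[int, int, str], ...]
    attach: tuple[tuple[int, str], ...]
    first_shell_types: tuple[str, ...] = ()


@dataclass(frozen=True)
class Rebond:
    """An order change on a bond between R and a preserved neighbour."""

    sub_type: str          # neighbour atom type on the substrate side
    old_order: str
    new_order: str | None  # None removes the bond
    prod_type: str = ""
    charge_delta: int = 0


@dataclass(frozen=True)
class GraphEdit:
    """Local subgraph replacement applied at the reaction centre."""

    rebonds: tuple[Rebond, ...] = ()
    deletes: tuple[FragmentSpec, ...] = ()
    attaches: tuple[FragmentSpec, ...] = ()
    r_charge_delta: int = 0


@dataclass(frozen=True)
class RDMPattern:
    r_substrate: str
    r_product: str
    d_substrate: tuple[str, ...]
    d_product: tuple[str, ...]
    m: tuple[str, ...]
    r_atom_index: int
    edit: GraphEdit | None = None
    valid: bool = True
    reason: str = ""


def _changed_bonds(sub: MolecularGraph, prod: MolecularGraph,
                   mapping: AtomMapping):
    """Bonds between mapped atoms whose order differs or that exist on one
    side only, expressed in substrate indices: (i, n, sub_order, prod_order)."""
    s2p = mapping.sub_to_prod
    p2s = mapping.prod_to_sub
    sub_orders = {frozenset((b.i, b.j)): b.order for b in sub.bonds}
    prod_orders = {frozenset((b.i, b.j)): b.order for b in prod.bonds}
    changed = {}
    for key, o1 in sub_orders.items():
        i, n = tuple(key)
        if i in s2p and n in s2p:
            o2 = prod_orders.get(frozenset((s2p[i], s2p[n])))
            if o2 != o1:
                changed[key] = (o1, o2)
    for key, o2 in prod_orders.items():
        j, m = tuple(key)
        if j in p2s and m in p2s:
            skey = frozenset((p2s[j], p2s[m]))
            if skey not in sub_orders:
                changed[skey] = (None, o2)
    return [(min(k), max(k), o1, o2) for k, (o1, o2) in sorted(changed.items(), key=lambda kv: sorted(kv[0]))]


def _components(items, footprints):
    """Union of items whose footprints intersect."""
    parent = list(range(len(items)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    node_owner: dict = {}
    for idx, fp in enumerate(footprints):
        for node in fp:
            if node in node_owner:
                ra, rb = find(node_owner[node]), find(idx)
                if ra != rb:
                    parent[rb] = ra
            else:
                node_owner[node] = idx
    comps: dict[int, list[int]] = {}
    for idx in range(len(items)):
        comps.setdefault(find(idx), []).append(idx)
    return list(comps.values())


def _fragment_spec(graph: MolecularGraph, atoms: list[int], r: int) -> FragmentSpec:
    local = {a: k for k, a in enumerate(sorted(atoms))}
    fatoms = tuple(
        (graph.atoms[a].element, graph.atoms[a].formal_charge, graph.atoms[a].aromatic)
        for a in sorted(atoms)
    )
    fbonds = []
    attach = []
    first_shell = []
    for a in sorted(atoms):
        for nb, order in graph.neighbors(a):
            if nb in local:
                if a < nb:
                    fbonds.append((local[a], local[nb], order))
            elif nb == r:
                attach.append((local[a], order))
                first_shell.append(graph.atoms[a].atom_type or "?")
    return FragmentSpec(
        atoms=fatoms,
        bonds=tuple(sorted(fbonds)),
        attach=tuple(sorted(attach)),
        first_shell_types=tuple(sorted(first_shell)),
    )


def _change_components(substrate: MolecularGraph, product: MolecularGraph,
                       mapping: AtomMapping):
    """Group the structural change into connected components.

    Returns ``(components, items)`` where each component is a list of
    indices into ``items`` and each item is ``("lost", a)``,
    ``("gained", b)`` or ``("bond", i, n, sub_order, prod_order)`` in
    substrate indices.
    """
    p2s = mapping.prod_to_sub
    changed = _changed_bonds(substrate, product, mapping)

    items: list[tuple] = []
    footprints: list[set] = []
    for a in mapping.lost:
        fp = {("s", a)}
        for nb, _ in substrate.neighbors(a):
            fp.add(("s", nb))
        items.append(("lost", a))
        footprints.append(fp)
    for b in mapping.gained:
        fp = {("p", b)}
        for nb, _ in product.neighbors(b):
            fp.add(("s", p2s[nb]) if nb in p2s else ("p", nb))
        items.append(("gained", b))
        footprints.append(fp)
    for i, n, o1, o2 in changed:
        items.append(("bond", i, n, o1, o2))
        footprints.append({("s", i), ("s", n)})
    if not items:
        return [], []
    return _components(items, footprints), items


def extract_rdm(substrate: MolecularGraph, product: MolecularGraph,
                mapping: AtomMapping) -> list[RDMPattern]:
    """Decompose the mapped structural change into RDM patterns.

    Returns one pattern per connected change component; an identical pair
    yields an empty list.  A pair yielding more than one pattern is
    multi-centre (the caller excludes it from operator generation), and a
    component whose edit cannot be anchored at a single R atom is returned
    with ``valid=False``.
    """
    if not mapping.pairs:
        return []
    s2p = mapping.sub_to_prod
    p2s = mapping.prod_to_sub

    comps, items = _change_components(substrate, product, mapping)
    if not items:
        return []

    sub_mol = substrate.to_rdkit()
    ranks = list(Chem.CanonicalRankAtoms(sub_mol, breakTies=True))

    patterns = []
    for comp in comps:
        comp_items = [items[k] for k in comp]
        lost = [it[1] for it in comp_items if it[0] == "lost"]
        gained = [it[1] for it in comp_items if it[0] == "gained"]
        bonds = [it[1:] for it in comp_items if it[0] == "bond"]

        anchors = set()
        for a in lost:
            anchors.update(nb for nb, _ in substrate.neighbors(a) if nb in s2p)
        for b in gained:
            anchors.update(p2s[nb] for nb, _ in product.neighbors(b) if nb in p2s)
        for i, n, _, _ in bonds:
            anchors.update(x for x in (i, n) if x in s2p)

        def representable_at(r: int) -> bool:
            for i, n, o1, _ in bonds:
                if r not in (i, n):
                    return False
                if o1 is None:
                    return False  # bond formation to a remote mapped atom
            for a in lost:
                if any(nb in s2p and nb != r for nb, _ in substrate.neighbors(a)):
                    return False
            for b in gained:
                if any(nb in p2s and p2s[nb] != r for nb, _ in product.neighbors(b)):
                    return False
            return True

        valid_rs = sorted(r for r in anchors if representable_at(r))
        if not valid_rs:
            patterns.append(RDMPattern(
                r_substrate="?", r_product="?", d_substrate=(), d_product=(),
                m=(), r_atom_index=-1, valid=False,
                reason="change not anchorable at a single reaction centre",
            ))
            continue

        changed_nb: dict[int, set[int]] = {}
        for i, n, _, _ in bonds:
            changed_nb.setdefault(i, set()).add(n)
            changed_nb.setdefault(n, set()).add(i)

        def matched_neighbors(r: int) -> list[int]:
            out = []
            for nb, _ in substrate.neighbors(r):
                if nb in s2p and nb not in lost and nb not in changed_nb.get(r, ()):
                    out.append(nb)
            return out

        r = min(valid_rs, key=lambda x: (-len(matched_neighbors(x)), ranks[x], x))
        rp = s2p[r]

        rebonds = []
        d_sub, d_prod = [], []
        for i, n, o1, o2 in bonds:
            other = n if i == r else i
            sub_t = substrate.atoms[other].atom_type or "?"
            prod_t = product.atoms[s2p[other]].atom_type or "?"
            rebonds.append(Rebond(
                sub_type=sub_t, old_order=o1, new_order=o2, prod_type=prod_t,
                charge_delta=product.atoms[s2p[other]].formal_charge
                - substrate.atoms[other].formal_charge,
            ))
            d_sub.append(sub_t)
            if o2 is not None:
                d_prod.append(prod_t)

        def fragment_groups(graph, atoms):
            remaining = set(atoms)
            groups = []
            while remaining:
                stack = [remaining.pop()]
                grp = set(stack)
                while stack:
                    cur = stack.pop()
                    for nb, _ in graph.neighbors(cur):
                        if nb in remaining:
                            remaining.discard(nb)
                            grp.add(nb)
                            stack.append(nb)
                groups.append(sorted(grp))
            return sorted(groups)

        deletes = tuple(
            _fragment_spec(substrate, grp, r) for grp in fragment_groups(substrate, lost)
        )
        attaches = tuple(
            _fragment_spec(product, grp, rp) for grp in fragment_groups(product, gained)
        )
        for spec in deletes:
            d_sub.extend(spec.first_shell_types)
        for spec in attaches:
            d_prod.extend(spec.first_shell_types)

        m_types = tuple(sorted(
            substrate.atoms[nb].atom_type or "?" for nb in matched_neighbors(r)
        ))
        edit = GraphEdit(
            rebonds=tuple(sorted(rebonds, key=lambda rb: (rb.sub_type, rb.old_order))),
            deletes=deletes,
            attaches=attaches,
            r_charge_delta=product.atoms[rp].formal_charge
            - substrate.atoms[r].formal_charge,
        )
        patterns.append(RDMPattern(
            r_substrate=substrate.atoms[r].atom_type or "?",
            r_product=product.atoms[rp].atom_type or "?",
            d_substrate=tuple(sorted(d_sub)),
            d_product=tuple(sorted(d_prod)),
            m=m_types,
            r_atom_index=r,
            edit=edit,
        ))
    return sorted(patterns, key=lambda p: p.r_atom_index)


# ---------------------------------------------------------------------------
# operators and the lookup table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Provenance:
    ec_numbers: tuple[str, ...]
    genes: tuple[str, ...]
    kegg_reaction: str
    reaction_id: str
    direction: str  # "forward" | "reverse"


@dataclass(frozen=True)
class OperatorOrigin:
    substrate_id: str
    substrate_key: str
    product_id: str
    product_key: str
    site: int


@dataclass(frozen=True)
class Operator:
    """A biotransformation lookup-table entry.

    ``key`` is the (R, M, D) environment required in a substrate; ``value``
    the (R, D) payload realised in the product; ``edit`` the explicit local
    graph edit; ``provenance`` the reactions the rule came from, aligned
    index-by-index with ``origins`` (their native substrate/product/site).
    """

    key: tuple[str, tuple[str, ...], tuple[str, ...]]
    value: tuple[str, tuple[str, ...]]
    edit: GraphEdit
    provenance: tuple[Provenance, ...]
    origins: tuple[OperatorOrigin, ...]

    @property
    def origin(self) -> OperatorOrigin:
        return self.origins[0]

    @property
    def sources(self) -> tuple[tuple[Provenance, OperatorOrigin], ...]:
        return tuple(zip(self.provenance, self.origins))

    @property
    def r_substrate(self) -> str:
        return self.key[0]

    @property
    def m(self) -> tuple[str, ...]:
        return self.key[1]

    @property
    def d_substrate(self) -> tuple[str, ...]:
        return self.key[2]


@dataclass
class OperatorTable:
    operators: list[Operator]
    n_entries: int = 0  # pre-merge entry count (one per reaction direction)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.n_entries:
            self.n_entries = len(self.operators)
        self._by_r: dict[str, list[Operator]] = {}
        for op in self.operators:
            self._by_r.setdefault(op.r_substrate, []).append(op)

    def lookup(self, r_type: str) -> list[Operator]:
        return self._by_r.get(r_type, [])

    def __len__(self) -> int:
        return len(self.operators)


def bundled_cofactor_keys() -> dict[str, str]:
    """Canonical structure keys of the bundled cofactor list (key → name)."""
    text = resources.files("metexpand.data").joinpath("cofactors.tsv").read_text()
    out = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#") or len(row) < 2:
            continue
        name, smiles = row[0], row[1]
        if smiles:
            out[chem.canonical_key(chem.parse_structure(smiles))] = name
    return out


def build_operator_table(
    model: MetabolicModel,
    cofactor_keys: Iterable[str] | None = None,
    cofactor_ids: Iterable[str] | None = None,
) -> OperatorTable:
    """Compile the operator lookup table from a model's reactions.

    For every reaction carrying a KEGG reaction id, the main reactant–
    product pair is the non-cofactor pair sharing the largest mapped
    substructure; single-centre RDM patterns become operators in the
    forward direction and, for reversible reactions, the reverse
    direction.  Cofactor-to-cofactor pairs and multi-centre pairs are
    skipped with a logged reason.
    """
    cof_keys = set(cofactor_keys) if cofactor_keys is not None else set(bundled_cofactor_keys())
    cof_ids = set(cofactor_ids or ())

    struct_keys = {
        mid: chem.canonical_key(met.structure)
        for mid, met in model.metabolites.items()
        if met.structure is not None
    }

    entries: list[Operator] = []
    skipped: list[tuple[str, str]] = []

    for rxn in model.reactions:
        if not rxn.kegg_ids:
            skipped.append((rxn.id, "no KEGG reaction id"))
            continue
        subs = [s for s in rxn.substrates
                if s in struct_keys and struct_keys[s] not in cof_keys and s not in cof_ids]
        prods = [p for p in rxn.products
                 if p in struct_keys and struct_keys[p] not in cof_keys and p not in cof_ids]
        if not subs or not prods:
            skipped.append((rxn.id, "no non-cofactor structured pair"))
            continue

        # main pair: largest mapped-atom count, then most type-exact
        # matches, then lexicographically smallest id pair
        best = None
        for s in subs:
            for p in prods:
                if struct_keys[s] == struct_keys[p]:
                    continue
                mapping = map_atoms(model.metabolites[s].structure,
                                    model.metabolites[p].structure)
                exact = sum(
                    1 for i, j in mapping.pairs
                    if model.metabolites[s].structure.atoms[i].atom_type
                    == model.metabolites[p].structure.atoms[j].atom_type
                )
                cand = (mapping.n_mapped, exact, s, p, mapping)
                if best is None or (cand[0], cand[1]) > (best[0], best[1]) or (
                    (cand[0], cand[1]) == (best[0], best[1])
                    and (s, p) < (best[2], best[3])
                ):
                    best = cand
        if best is None:
            skipped.append((rxn.id, "main pair degenerate (identical structures)"))
            continue
        _, _, s_id, p_id, mapping = best

        directions = [("forward", s_id, p_id, mapping)]
        if rxn.reversible:
            directions.append(("reverse", p_id, s_id, mapping.inverse()))

        for direction, a_id, b_id, mp in directions:
            a = model.metabolites[a_id].structure
            b = model.metabolites[b_id].structure
            patterns = extract_rdm(a, b, mp)
            if not patterns:
                skipped.append((rxn.id, f"{direction}: identical pair, no pattern"))
                continue
            if len(patterns) > 1:
                skipped.append((rxn.id, f"{direction}: multi-centre pair "
                                        f"({len(patterns)} reaction centres)"))
                continue
            pat = patterns[0]
            if not pat.valid or pat.edit is None:
                skipped.append((rxn.id, f"{direction}: {pat.reason or 'invalid pattern'}"))
                continue
            prov = Provenance(
                ec_numbers=rxn.ec_numbers,
                genes=rxn.genes,
                kegg_reaction=rxn.kegg_ids[0],
                reaction_id=rxn.id,
                direction=direction,
            )
            entries.append(Operator(
                key=(pat.r_substrate, pat.m, pat.d_substrate),
                value=(pat.r_product, pat.d_product),
                edit=pat.edit,
                provenance=(prov,),
                origins=(OperatorOrigin(
                    substrate_id=a_id,
                    substrate_key=struct_keys[a_id],
                    product_id=b_id,
                    product_key=struct_keys[b_id],
                    site=pat.r_atom_index,
                ),),
            ))

    # merge exact duplicates (same key, value and edit), keeping all
    # provenance/origin pairs
    merged: dict[tuple, Operator] = {}
    for op in entries:
        mkey = (op.key, op.value, op.edit)
        if mkey in merged:
            prev = merged[mkey]
            sources = {**dict(prev.sources), **dict(op.sources)}
            ordered = tuple(sorted(
                sources.items(),
                key=lambda pv: (pv[0].reaction_id, pv[0].direction)))
            merged[mkey] = Operator(
                key=prev.key, value=prev.value, edit=prev.edit,
                provenance=tuple(p for p, _ in ordered),
                origins=tuple(o for _, o in ordered),
            )
        else:
            merged[mkey] = op
    table = OperatorTable(
        operators=list(merged.values()), n_entries=len(entries), skipped=skipped,
    )
    for rid, reason in skipped:
        logger.info("operator extraction skipped %s: %s", rid, reason)
    logger.info("operator table: %d entries, %d after merging duplicates",
                table.n_entries, len(table))
    return table
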