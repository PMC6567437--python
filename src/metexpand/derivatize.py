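"""Apply biotransformation operators to metabolites.

``find_sites`` locates atoms whose radius-1 environment satisfies an
operator's (R, M, D) key; ``apply_operator`` performs the operator's local
graph edit at a site, rebalances implicit hydrogens and validates
valences; ``enumerate_derivatives`` sweeps an operator table over a
substrate pool and returns the deduplicated list of putative promiscuous
products with full provenance.

Application is single-step: derivatives are never re-fed as substrates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from rdkit import Chem

from . import chem
from .chem import Bond, MolecularGraph, TypedAtom, ValenceError
from .model_io import MetabolicModel
from .rdm import FragmentSpec, Operator, OperatorTable, Provenance

logger = logging.getLogger(__name__)

__all__ = [
    "DerivativeError",
    "PredictedDerivative",
    "find_sites",
    "apply_operator",
    "enumerate_derivatives",
]


class DerivativeError(ValueError):
    pass


@dataclass(frozen=True)
class PredictedDerivative:
    """A putative promiscuous product with provenance."""

    parent_id: str
    parent_key: str
    site: int
    product_key: str
    product: MolecularGraph
    provenance: Provenance
    known_id: str | None = None
    already_in_model: bool = False
    self_transformation: bool = False

    def sort_key(self):
        return (self.parent_id, self.product_key,
                self.provenance.reaction_id, self.provenance.direction, self.site)


# ---------------------------------------------------------------------------
# site matching
# ---------------------------------------------------------------------------

def _match_fragment(g: MolecularGraph, r: int, spec: FragmentSpec,
                    used: set[int]) -> list[int] | None:
    """Match a deletable fragment hanging off ``r``: an injective,
    severable embedding (fragment atoms bond only within the match or to
    R).  Returns matched graph atom indices in fragment-local order."""
    n = len(spec.atoms)
    adj: dict[int, list[tuple[int, str]]] = {k: [] for k in range(n)}
    for a, b, order in spec.bonds:
        adj[a].append((b, order))
        adj[b].append((a, order))
    attach_by_local: dict[int, list[str]] = {}
    for local, order in spec.attach:
        attach_by_local.setdefault(local, []).append(order)

    assign: dict[int, int] = {}
    taken: set[int] = set()

    def atom_ok(local: int, gidx: int) -> bool:
        el, charge, _ = spec.atoms[local]
        atom = g.atoms[gidx]
        if atom.element != el or atom.formal_charge != charge:
            return False
        # severability: neighbours must be r, or eligible fragment atoms
        return True

    def neighbors_to_r(gidx: int) -> list[str]:
        return [order for nb, order in g.neighbors(gidx) if nb == r]

    order_of = sorted(range(n), key=lambda k: (k not in attach_by_local, k))

    def backtrack(pos: int) -> bool:
        if pos == len(order_of):
            # severability check on the complete assignment
            matched = set(assign.values())
            for local, gidx in assign.items():
                for nb, order in g.neighbors(gidx):
                    if nb == r:
                        continue
                    if nb not in matched:
                        return False
            # bond consistency
            for a, b, order in spec.bonds:
                ga, gb = assign[a], assign[b]
                if not any(nb == gb and o == order for nb, o in g.neighbors(ga)):
                    return False
            return True
        local = order_of[pos]
        required_attach = sorted(attach_by_local.get(local, []))
        if required_attach:
            candidates = [
                nb for nb, order in g.neighbors(r)
                if sorted(neighbors_to_r(nb)) == required_attach
            ]
        else:
            candidates = []
            for al, gidx in assign.items():
                for bl, order in adj[al]:
                    if bl == local:
                        candidates.extend(
                            nb for nb, o in g.neighbors(gidx) if o == order
                        )
            candidates = sorted(set(candidates))
        for gidx in candidates:
            if gidx in taken or gidx in used or gidx == r:
                continue
            if not atom_ok(local, gidx):
                continue
            assign[local] = gidx
            taken.add(gidx)
            if backtrack(pos + 1):
                return True
            del assign[local]
            taken.discard(gidx)
        return False

    if backtrack(0):
        return [assign[k] for k in range(n)]
    return None


@dataclass
class _SitePlan:
    site: int
    rebond_targets: list[int]           # graph atom per Rebond, in order
    delete_matches: list[list[int]]     # graph atoms per delete fragment


def _plan_site(op: Operator, g: MolecularGraph, site: int) -> _SitePlan | None:
    atom = g.atoms[site]
    if atom.atom_type != op.r_substrate:
        return None
    used: set[int] = set()
    rebond_targets: list[int] = []
    for rb in op.edit.rebonds:
        found = None
        for nb, order in sorted(g.neighbors(site)):
            if nb in used or order != rb.old_order:
                continue
            if g.atoms[nb].atom_type == rb.sub_type:
                found = nb
                break
        if found is None:
            return None
        used.add(found)
        rebond_targets.append(found)
    delete_matches: list[list[int]] = []
    for spec in op.edit.deletes:
        match = _match_fragment(g, site, spec, used)
        if match is None:
            return None
        used.update(match)
        delete_matches.append(match)
    # the preserved (M) environment must be available among the remaining
    # first-shell neighbours
    remaining = [g.atoms[nb].atom_type for nb, _ in g.neighbors(site) if nb not in used]
    need = list(op.m)
    for t in need:
        if t in remaining:
            remaining.remove(t)
        else:
            return None
    return _SitePlan(site=site, rebond_targets=rebond_targets,
                     delete_matches=delete_matches)


def find_sites(op: Operator, g: MolecularGraph) -> list[int]:
    """All atoms matching the operator key; automorphism-equivalent
    duplicates are collapsed to the lowest-index representative."""
    hits = [a.index for a in g.atoms if _plan_site(op, g, a.index) is not None]
    if len(hits) <= 1:
        return hits
    ranks = list(Chem.CanonicalRankAtoms(g.to_rdkit(), breakTies=False))
    by_rank: dict[int, int] = {}
    for idx in hits:
        r = ranks[idx]
        if r not in by_rank or idx < by_rank[r]:
            by_rank[r] = idx
    return sorted(by_rank.values())


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def apply_operator(op: Operator, g: MolecularGraph, site: int) -> MolecularGraph:
    """Apply the operator's graph edit at ``site`` and return the product.

    Implicit hydrogens are rebalanced from default valences; a valence
    violation after the edit raises :class:`DerivativeError`.
    """
    plan = _plan_site(op, g, site)
    if plan is None:
        raise DerivativeError(
            f"atom {site} does not match operator key {op.key}"
        )

    removed: set[int] = set()
    for match in plan.delete_matches:
        removed.update(match)

    rebond_orders = {}
    charge_deltas = {site: op.edit.r_charge_delta}
    for rb, target in zip(op.edit.rebonds, plan.rebond_targets):
        rebond_orders[frozenset((site, target))] = rb.new_order
        charge_deltas[target] = charge_deltas.get(target, 0) + rb.charge_delta

    atoms: list[tuple[str, int, bool]] = []
    index_map: dict[int, int] = {}
    for a in g.atoms:
        if a.index in removed:
            continue
        index_map[a.index] = len(atoms)
        atoms.append((
            a.element,
            a.formal_charge + charge_deltas.get(a.index, 0),
            a.aromatic,
        ))

    bonds: list[tuple[int, int, str]] = []
    for b in g.bonds:
        if b.i in removed or b.j in removed:
            continue
        key = frozenset((b.i, b.j))
        if key in rebond_orders:
            new_order = rebond_orders[key]
            if new_order is None:
                continue
            bonds.append((index_map[b.i], index_map[b.j], new_order))
        else:
            bonds.append((index_map[b.i], index_map[b.j], b.order))

    for spec in op.edit.attaches:
        base = len(atoms)
        for el, charge, aromatic in spec.atoms:
            atoms.append((el, charge, aromatic))
        for a, b, order in spec.bonds:
            bonds.append((base + a, base + b, order))
        for local, order in spec.attach:
            bonds.append((index_map[site], base + local, order))

    raw = MolecularGraph(
        atoms=tuple(
            TypedAtom(index=i, element=el, implicit_h=0, formal_charge=ch,
                      aromatic=ar)
            for i, (el, ch, ar) in enumerate(atoms)
        ),
        bonds=tuple(Bond(i, j, o) for i, j, o in bonds),
    )
    try:
        product = chem.from_rdkit(raw.to_rdkit(recompute_h=True))
    except ValenceError as exc:
        raise DerivativeError(f"edit at atom {site} gives invalid product: {exc}")

    # a bond removal can split the molecule; keep the reaction-centre part
    comps = product.connected_components()
    if len(comps) > 1:
        keep = next(c for c in comps if index_map[site] in c)
        order = sorted(keep)
        remap = {old: new for new, old in enumerate(order)}
        product = chem.assign_atom_types(MolecularGraph(
            atoms=tuple(
                TypedAtom(index=remap[a.index], element=a.element,
                          implicit_h=a.implicit_h,
                          formal_charge=a.formal_charge, aromatic=a.aromatic)
                for a in product.atoms if a.index in keep
            ),
            bonds=tuple(
                Bond(remap[b.i], remap[b.j], b.order)
                for b in product.bonds if b.i in keep and b.j in keep
            ),
        ))
    return product


# ---------------------------------------------------------------------------
# enumeration over a pool
# ---------------------------------------------------------------------------

def enumerate_derivatives(
    table: OperatorTable,
    pool: Iterable[str],
    model: MetabolicModel,
    known_compounds: Mapping[str, str] | None = None,
) -> list[PredictedDerivative]:
    """All (operator, metabolite, site) products over the pool.

    Products are deduplicated by (parent, product key, provenance);
    products identical to a model metabolite are kept but flagged
    ``already_in_model``; products whose canonical key occurs in
    ``known_compounds`` carry the corresponding external id.  Products
    equal to their parent and valence-invalid edits are dropped with a
    logged reason.
    """
    known = dict(known_compounds or {})
    model_keys = {
        chem.canonical_key(met.structure)
        for met in model.metabolites.values() if met.structure is not None
    }
    out: dict[tuple, PredictedDerivative] = {}
    for parent_id in sorted(set(pool)):
        met = model.metabolites.get(parent_id)
        if met is None or met.structure is None:
            continue
        parent_key = chem.canonical_key(met.structure)
        for op in table.operators:
            for site in find_sites(op, met.structure):
                try:
                    product = apply_operator(op, met.structure, site)
                except DerivativeError as exc:
                    logger.debug("skip %s site %d: %s", parent_id, site, exc)
                    continue
                pkey = chem.canonical_key(product)
                if pkey == parent_key:
                    logger.debug("skip %s site %d: product equals parent",
                                 parent_id, site)
                    continue
                for prov, origin in op.sources:
                    self_tx = (origin.substrate_key == parent_key
                               and origin.product_key == pkey)
                    dedup = (parent_id, pkey, prov)
                    if dedup in out:
                        continue
                    out[dedup] = PredictedDerivative(
                        parent_id=parent_id,
                        parent_key=parent_key,
                        site=site,
                        product_key=pkey,
                        product=product,
                        provenance=prov,
                        known_id=known.get(pkey),
                        already_in_model=pkey in model_keys,
                        self_transformation=self_tx,
                    )
    return sorted(out.values(), key=PredictedDerivative.sort_key)
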