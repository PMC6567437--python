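"""Synthetic test universes with planted enzyme promiscuity.

Molecules are decorated carbon chains rendered from a small scaffold
grammar (hydroxyl, amino, keto, carboxyl and phosphate decorations), so
that every native reaction is a single-centre edit drawn from four
archetypes — alcohol oxidation, terminal-hydroxyl phosphorylation,
terminal decarboxylation and reductive amination — each with its toy
cofactor couple.  Promiscuous products are planted by constructing, for
a chosen native reaction, a novel substrate whose radius-2 environment
around the reaction site matches the native substrate's, guaranteeing by
construction that the extracted operator applies to it; the planted
product is inserted into the synthetic metabolome and the reference
index is populated to realise a requested C1–C4 category mix.

The generator validates its own universe: grammar-level enumeration of
every archetype application over every model metabolite must reach each
metabolome compound only through the intended substrate, so end-to-end
recall and label accuracy of 100% are well-defined targets and any miss
is a pipeline defect, not fixture ambiguity.

Generation is deterministic under a single integer seed threading one
``random.Random`` instance; no global randomness is used.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .. import chem
from ..chem import MolecularGraph
from ..curation import EnzymeRef, ReferenceIndex
from ..matcher import MetaboliteRecord, XrefTable
from ..model_io import (ConcentrationTable, MetabolicModel, Metabolite,
                        Reaction)

__all__ = ["Scaffold", "ToyUniverse", "PlantedTruth", "generate_toy_universe",
           "write_universe", "COFACTOR_SMILES"]

# decoration vocabulary: position -> one decoration
_DECOS = ("oh", "nh2", "keto", "cooh", "opo3")

_DECO_SMILES = {
    None: "",
    "oh": "(O)",
    "nh2": "(N)",
    "keto": "(=O)",
    "cooh": "(C(=O)O)",
    "opo3": "(OP(=O)(O)O)",
}

COFACTOR_SMILES = {
    "tnad_ox": "CC(=O)C1CCCCC1",   # toy redox couple: differs by 2 H
    "tnad_red": "CC(O)C1CCCCC1",
    "tatp": "OP(=O)(O)OP(=O)(O)OCC1CCCCC1",  # toy phosphoryl donor couple
    "tadp": "OP(=O)(O)OCC1CCCCC1",
    "tco2": "O=C=O",
    "tnh3": "N",
    "th2o": "O",
}

# directed archetypes: name -> (deco before, deco after, terminal-only,
#                               substrate-side cofactors, product-side)
_ARCHETYPES = {
    "oxidation": ("oh", "keto", False,
                  (("tnad_ox", 1),), (("tnad_red", 1),)),
    "phosphorylation": ("oh", "opo3", True,
                        (("tatp", 1),), (("tadp", 1),)),
    "decarboxylation": ("cooh", None, True,
                        (), (("tco2", 1),)),
    "amination": ("keto", "nh2", False,
                  (("tnh3", 1), ("tnad_red", 1)),
                  (("th2o", 1), ("tnad_ox", 1))),
}
_EC_FAMILY = {
    "oxidation": "1.1.1",
    "phosphorylation": "2.7.1",
    "decarboxylation": "4.1.1",
    "amination": "1.4.1",
}


@dataclass(frozen=True)
class Scaffold:
    """A decorated carbon chain; positions are 1-based."""

    length: int
    decorations: tuple[tuple[int, str], ...] = ()

    def deco(self, pos: int) -> str | None:
        return dict(self.decorations).get(pos)

    def with_deco(self, pos: int, deco: str | None) -> "Scaffold":
        d = {p: x for p, x in self.decorations if p != pos}
        if deco is not None:
            d[pos] = deco
        return Scaffold(self.length, tuple(sorted(d.items())))

    def extended(self, extra: int) -> "Scaffold":
        return Scaffold(self.length + extra, self.decorations)

    def flipped(self) -> "Scaffold":
        return Scaffold(self.length, tuple(sorted(
            (self.length + 1 - p, x) for p, x in self.decorations)))

    def normal_form(self) -> "Scaffold":
        flip = self.flipped()
        return min(self, flip, key=lambda s: s.decorations)

    def smiles(self) -> str:
        return "".join(
            "C" + _DECO_SMILES[self.deco(p)] for p in range(1, self.length + 1)
        )

    def window(self, pos: int, radius: int = 2) -> tuple:
        """Radius-``radius`` decoration context around ``pos`` (chain ends
        included), which pins down every atom type the operator key sees."""
        out = []
        for d in range(-radius, radius + 1):
            q = pos + d
            out.append(self.deco(q) if 1 <= q <= self.length else "END")
        return tuple(out)


def _applications(s: Scaffold):
    """All grammar-level directed-archetype applications on a scaffold,
    including the reverse directions (native reactions are reversible)."""
    apps = []
    for name, (before, after, terminal, _, _) in _ARCHETYPES.items():
        for pos in range(1, s.length + 1):
            is_terminal = pos in (1, s.length)
            if terminal and not is_terminal:
                continue
            if name in ("oxidation", "amination") and is_terminal and \
                    s.length > 1:
                # keep redox/amination interior so products stay ketones
                continue
            if s.deco(pos) == before:
                apps.append((name, "forward", pos, s.with_deco(pos, after)))
            if s.deco(pos) == after:
                apps.append((name, "reverse", pos, s.with_deco(pos, before)))
    return apps


@dataclass(frozen=True)
class PlantedTruth:
    substrate_id: str
    substrate_key: str
    product_key: str
    product_primary_id: str
    source_reaction_id: str
    direction: str
    category: str


@dataclass
class ToyUniverse:
    model: MetabolicModel
    concentrations: ConcentrationTable
    metabolome: list[MetaboliteRecord]
    xrefs: XrefTable
    known_compounds: dict[str, str]
    reference: ReferenceIndex
    planted: list[PlantedTruth]
    cofactor_ids: tuple[str, ...]
    threshold_uM: float = 1.0


class _Builder:
    def __init__(self, rng: random.Random):
        self.rng = rng
        self.mets: dict[str, Scaffold] = {}           # id -> scaffold
        self.keys: dict[str, str] = {}                # id -> canonical key
        self.graphs: dict[str, MolecularGraph] = {}
        self.by_form: set[tuple] = set()
        self.counter = 0

    def add(self, scaffold: Scaffold, prefix: str = "m") -> str | None:
        nf = scaffold.normal_form()
        if nf.decorations is not None and (nf.length, nf.decorations) in self.by_form:
            return None
        g = chem.parse_structure(scaffold.smiles())
        key = chem.canonical_key(g)
        if key in self.keys.values():
            return None
        self.counter += 1
        mid = f"{prefix}{self.counter:03d}"
        self.mets[mid] = scaffold
        self.keys[mid] = key
        self.graphs[mid] = g
        self.by_form.add((nf.length, nf.decorations))
        return mid

    def id_of_key(self, key: str) -> str | None:
        for mid, k in self.keys.items():
            if k == key:
                return mid
        return None


def _random_scaffold(rng: random.Random) -> Scaffold:
    n = rng.randint(3, 6)
    s = Scaffold(n)
    for pos in range(1, n + 1):
        if rng.random() < 0.45:
            terminal = pos in (1, n)
            choices = ["oh", "nh2"] + (["cooh"] if terminal else ["keto"])
            s = s.with_deco(pos, rng.choice(choices))
    return s


def _plant_substrate(rng: random.Random, origin: Scaffold, pos: int,
                     builder: _Builder) -> tuple[Scaffold, int] | None:
    """A novel scaffold sharing the radius-2 window of ``origin`` at
    ``pos`` (flipping first when the site hugs the right end so all
    mutations can go rightwards)."""
    if pos > origin.length - pos + 1:
        origin = origin.flipped()
        pos = origin.length + 1 - pos
    target = origin.window(pos)
    for _ in range(60):
        cand = origin
        if rng.random() < 0.7 and cand.length < 8:
            cand = cand.extended(rng.randint(1, 2))
        far = [q for q in range(pos + 3, cand.length + 1)]
        rng.shuffle(far)
        for q in far[: rng.randint(0, 2) or 1]:
            terminal = q in (1, cand.length)
            choices = [None, "oh", "nh2"] + (["cooh"] if terminal else [])
            cand = cand.with_deco(q, rng.choice(choices))
        if cand.window(pos) != target:
            continue
        if cand.normal_form() == origin.normal_form():
            continue
        if (cand.length, cand.normal_form().decorations) in builder.by_form:
            continue
        return cand, pos
    return None


def generate_toy_universe(
    seed: int,
    n_scaffolds: int = 14,
    n_reactions: int = 10,
    promiscuity_rate: float = 2.0,
    category_mix: Mapping[str, float] | None = None,
) -> ToyUniverse:
    """Generate a deterministic toy universe with planted promiscuity.

    ``promiscuity_rate`` is the expected number of planted promiscuous
    products per native reaction (the default plants 20 products over 10
    reactions); ``category_mix`` gives the intended C1–C4 proportions and
    must sum to 1.  Raises ``ValueError`` for an infeasible configuration.
    """
    if n_scaffolds <= 0 or n_reactions <= 0 or promiscuity_rate < 0:
        raise ValueError("generator parameters must be positive")
    mix = dict(category_mix or {"C1": 0.25, "C2": 0.25, "C3": 0.25, "C4": 0.25})
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("category_mix must sum to 1")
    unknown = set(mix) - {"C1", "C2", "C3", "C4"}
    if unknown:
        raise ValueError(f"unknown categories in mix: {sorted(unknown)}")

    rng = random.Random(seed)
    builder = _Builder(rng)

    # -- base metabolites ----------------------------------------------
    guard = 0
    while len(builder.mets) < n_scaffolds and guard < 400:
        guard += 1
        builder.add(_random_scaffold(rng))

    # -- native reactions ----------------------------------------------
    reactions: list[Reaction] = []
    native_info: dict[str, tuple[str, str, int, str, str]] = {}
    # reaction id -> (archetype, substrate id, position, product id, gene)
    native_pairs: set[frozenset[str]] = set()

    def add_native(sub_id: str, arch: str, pos: int, genes: tuple[str, ...],
                   ec_minor: int) -> str | None:
        before, after, _, co_subs, co_prods = _ARCHETYPES[arch]
        sub = builder.mets[sub_id]
        prod_scaffold = sub.with_deco(pos, after)
        prod_id = builder.id_of_key(
            chem.canonical_key(chem.parse_structure(prod_scaffold.smiles())))
        if prod_id is None:
            prod_id = builder.add(prod_scaffold)
        if prod_id is None or prod_id == sub_id:
            return None
        pair = frozenset((builder.keys[sub_id], builder.keys[prod_id]))
        if pair in native_pairs:
            return None
        native_pairs.add(pair)
        rid = f"TR{len(reactions) + 1:03d}"
        stoich = {sub_id: -1.0, prod_id: 1.0}
        for cid, c in co_subs:
            stoich[cid] = stoich.get(cid, 0.0) - c
        for cid, c in co_prods:
            stoich[cid] = stoich.get(cid, 0.0) + c
        reactions.append(Reaction(
            id=rid,
            name=f"{arch} of {sub_id}",
            ec_numbers=(f"{_EC_FAMILY[arch]}.{ec_minor}",),
            genes=genes,
            kegg_ids=(f"R9{len(reactions) + 1:04d}",),
            stoichiometry=stoich,
            raw_stoichiometry={f"{mid}_c": c for mid, c in stoich.items()},
            reversible=True,
        ))
        native_info[rid] = (arch, sub_id, pos, prod_id, genes[0])
        return rid

    guard = 0
    gene_no = 1000
    ec_minor = 0
    while sum(1 for _ in native_info) < n_reactions and guard < 600:
        guard += 1
        sub_id = rng.choice(sorted(builder.mets))
        apps = [a for a in _applications(builder.mets[sub_id])
                if a[1] == "forward"]
        if not apps:
            continue
        arch, _, pos, _ = rng.choice(apps)
        gene_no += 1
        ec_minor += 1
        add_native(sub_id, arch, pos, (f"b{gene_no}",), ec_minor)
    if len(native_info) < n_reactions:
        raise ValueError("could not realise the requested number of "
                         "native reactions from the scaffold pool")

    # -- planted promiscuity -------------------------------------------
    n_planted = round(promiscuity_rate * n_reactions)
    quotas = {c: int(mix.get(c, 0) * n_planted) for c in ("C1", "C2", "C3", "C4")}
    # largest-remainder completion
    while sum(quotas.values()) < n_planted:
        rem = sorted(
            ("C1", "C2", "C3", "C4"),
            key=lambda c: (quotas[c] - mix.get(c, 0) * n_planted, c),
        )
        quotas[rem[0]] += 1

    organism_pairs: set[frozenset[str]] = set()
    other_pairs: set[frozenset[str]] = set()
    planted: list[PlantedTruth] = []
    planted_products: dict[str, str] = {}  # product key -> planted substrate id

    # grammar-level reachability of product keys from model metabolites,
    # maintained incrementally so planted products stay unambiguous
    reach: dict[str, set[str]] = {}

    def app_keys(scaffold: Scaffold) -> set[str]:
        return {
            chem.canonical_key(chem.parse_structure(prod.smiles()))
            for _, _, _, prod in _applications(scaffold)
        }

    def register(mid: str) -> None:
        for key in app_keys(builder.mets[mid]):
            reach.setdefault(key, set()).add(mid)

    for mid in sorted(builder.mets):
        register(mid)

    categories = [c for c in ("C1", "C2", "C3", "C4") for _ in range(quotas[c])]
    rng.shuffle(categories)
    rids = sorted(native_info)
    guard = 0
    while categories and guard < 1500:
        guard += 1
        category = categories[0]
        rid = rng.choice(rids)
        arch, nat_sub, pos, nat_prod, _ = native_info[rid]
        got = _plant_substrate(rng, builder.mets[nat_sub], pos, builder)
        if got is None:
            continue
        scaffold, p = got
        before, after, _, _, _ = _ARCHETYPES[arch]
        prod_scaffold = scaffold.with_deco(p, after)
        prod_g = chem.parse_structure(prod_scaffold.smiles())
        prod_key = chem.canonical_key(prod_g)
        if prod_key in planted_products or prod_key in builder.keys.values():
            continue
        # unambiguity: no existing metabolite may already reach the new
        # product, and the new substrate must not reach earlier planted
        # products
        if reach.get(prod_key):
            continue
        sub_app = app_keys(scaffold)
        if (sub_app - {prod_key}) & set(planted_products):
            continue
        if category == "C1" and app_keys(prod_scaffold) & set(planted_products):
            continue
        sub_id = builder.add(scaffold, prefix="x")
        if sub_id is None:
            continue
        sub_key = builder.keys[sub_id]
        pair = frozenset((sub_key, prod_key))
        if pair in native_pairs:
            continue

        primary = f"P{2000 + len(planted):04d}"
        if category == "C1":
            # a parallel native route with a different gene realises C1
            prod_id = builder.add(prod_scaffold)
            if prod_id is None:
                continue
            gene_no += 1
            ec_minor += 1
            par = add_native(sub_id, arch, p, (f"b{gene_no}",), ec_minor)
            if par is None:
                continue
            register(prod_id)
        elif category == "C2":
            organism_pairs.add(pair)
        elif category == "C3":
            other_pairs.add(pair)
        register(sub_id)
        planted.append(PlantedTruth(
            substrate_id=sub_id,
            substrate_key=sub_key,
            product_key=prod_key,
            product_primary_id=primary,
            source_reaction_id=rid,
            direction="forward",
            category=category,
        ))
        planted_products[prod_key] = sub_id
        categories.pop(0)
    if categories:
        raise ValueError(
            f"could not realise category mix; unplaced: {categories}")

    # defensive re-validation over the final metabolite set
    for t in planted:
        sources = reach.get(t.product_key, set())
        extra = {
            mid for mid in sources
            if mid != t.substrate_id and builder.keys[mid] != t.substrate_key
            and builder.keys[mid] != t.product_key
        }
        if extra:
            raise ValueError(
                f"ambiguous universe: planted product of {t.substrate_id} "
                f"also reachable from {sorted(extra)}; use another seed")

    # -- assemble the model --------------------------------------------
    metabolites: dict[str, Metabolite] = {}
    for mid in sorted(builder.mets):
        g = builder.graphs[mid]
        f = chem.formula_of(g)
        metabolites[mid] = Metabolite(
            id=mid, name=mid, compartments=("c",),
            instance_ids={"c": f"{mid}_c"},
            formula=f.to_string(), charge=f.charge, structure=g,
        )
    for cid, smi in COFACTOR_SMILES.items():
        g = chem.parse_structure(smi)
        f = chem.formula_of(g)
        metabolites[cid] = Metabolite(
            id=cid, name=cid, compartments=("c",),
            instance_ids={"c": f"{cid}_c"},
            formula=f.to_string(), charge=f.charge, structure=g,
        )
    genes = tuple(sorted({g for r in reactions for g in r.genes}))
    model = MetabolicModel(id=f"toy{seed}", metabolites=metabolites,
                           reactions=reactions, genes=genes)
    model.validate()

    # -- concentrations: planted + native substrates are high ----------
    conc: dict[str, float] = {}
    high = {t.substrate_id for t in planted} | {
        info[1] for info in native_info.values()}
    for mid in sorted(builder.mets):
        if mid in high:
            conc[mid] = round(rng.uniform(2.0, 120.0), 3)
        else:
            conc[mid] = round(rng.uniform(0.01, 0.9), 3)
    concentrations = ConcentrationTable(conc)

    # -- metabolome + xref table + known compounds ---------------------
    records: list[MetaboliteRecord] = []
    xref_entries: dict[tuple[str, str], str] = {}
    known: dict[str, str] = {}

    def add_record(key: str, name: str, formula: str, primary: str,
                   consistent: bool = True, with_structure: bool | None = None):
        i = len(records)
        db_id = f"TM{i:04d}"
        sources = ["inchikey", "kegg", "cas"]
        xrefs = {}
        for k, src in enumerate(sources):
            xid = f"{src[:3].upper()}{i:04d}"
            xrefs[src] = xid
            xref_entries[(src, xid)] = primary
        declared = primary
        if not consistent:
            declared = primary + "X"  # majority overrides the declared id
        use_structure = (rng.random() < 0.5 if with_structure is None
                         else with_structure)
        records.append(MetaboliteRecord(
            db_id=db_id, name=name, formula=formula,
            declared_primary_id=declared, xrefs=xrefs,
            structure_key=key if use_structure else None,
        ))
        known[key] = primary

    for t in planted:
        prod_formula = chem.formula_of(
            chem.parse_structure(_product_smiles(builder, t)))
        add_record(t.product_key, f"planted-{t.substrate_id}",
                   prod_formula.to_string(), t.product_primary_id,
                   consistent=(rng.random() < 0.8))
    # an unresolved record: conflicting votes, never matches anything
    records.append(MetaboliteRecord(
        db_id=f"TM{len(records):04d}", name="unresolvable", formula="C2H6O",
        declared_primary_id="P9001",
        xrefs={"inchikey": "UNR1", "kegg": "UNR2"},
    ))
    xref_entries[("inchikey", "UNR1")] = "P9002"
    xref_entries[("kegg", "UNR2")] = "P9003"

    for mid in sorted(builder.mets):
        known.setdefault(builder.keys[mid], f"P{5000 + hash(mid) % 1000:04d}")

    # -- reference index ------------------------------------------------
    model_keys = frozenset(
        chem.canonical_key(m.structure) for m in metabolites.values()
        if m.structure is not None
    )
    model_rxn_index: dict[frozenset[str], list[EnzymeRef]] = {}
    for rxn in reactions:
        arch, nat_sub, _, nat_prod, _ = native_info[rxn.id]
        pair = frozenset((builder.keys[nat_sub], builder.keys[nat_prod]))
        model_rxn_index.setdefault(pair, []).append(
            EnzymeRef(rxn.ec_numbers, rxn.genes))
    reference = ReferenceIndex(
        model_metabolite_keys=model_keys,
        model_reactions={p: tuple(v) for p, v in model_rxn_index.items()},
        organism_pairs=frozenset(organism_pairs),
        other_organism_pairs=frozenset(other_pairs),
    )

    return ToyUniverse(
        model=model,
        concentrations=concentrations,
        metabolome=records,
        xrefs=XrefTable(xref_entries),
        known_compounds=known,
        reference=reference,
        planted=planted,
        cofactor_ids=tuple(sorted(COFACTOR_SMILES)),
    )


def _product_smiles(builder: _Builder, t: PlantedTruth) -> str:
    """Reconstruct the planted product scaffold from the substrate and
    the source archetype (used for record formulas)."""
    # the product key was derived from substrate scaffold + archetype at
    # planting time; recompute by searching the substrate's applications
    scaffold = builder.mets[t.substrate_id]
    for _, _, _, prod in _applications(scaffold):
        if chem.canonical_key(chem.parse_structure(prod.smiles())) == t.product_key:
            return prod.smiles()
    raise RuntimeError("planted product not reconstructible")


def write_universe(universe: ToyUniverse, outdir: str | Path) -> dict[str, Path]:
    """Write the universe as a file bundle in the pipeline's own formats
    (BiGG-style JSON + SMILES sidecar + TSVs), so fixtures double as
    format documentation.  Returns the paths keyed by role."""
    import json

    import pandas as pd

    from ..model_io import save_model

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": outdir / "model.json",
        "structures": outdir / "structures.tsv",
        "concentrations": outdir / "concentrations.tsv",
        "metabolome": outdir / "metabolome.tsv",
        "xrefs": outdir / "xrefs.tsv",
        "known": outdir / "known_compounds.tsv",
        "reference": outdir / "reference_index.json",
        "cofactors": outdir / "cofactor_ids.txt",
        "planted": outdir / "planted_truth.tsv",
    }
    from rdkit import Chem as RDChem

    save_model(universe.model, paths["model"])
    rows = [
        (mid, RDChem.MolToSmiles(m.structure.to_rdkit()))
        for mid, m in sorted(universe.model.metabolites.items())
        if m.structure is not None
    ]
    pd.DataFrame(rows).to_csv(paths["structures"], sep="\t", header=False,
                              index=False)
    universe.concentrations.to_tsv(paths["concentrations"])
    pd.DataFrame([
        {
            "id": r.db_id, "name": r.name, "formula": r.formula,
            "pubchem": r.declared_primary_id or "",
            **{src: r.xrefs.get(src, "") for src in
               ("inchikey", "kegg", "cas", "chebi", "biocyc")},
            "structure_key": r.structure_key or "",
        }
        for r in universe.metabolome
    ]).to_csv(paths["metabolome"], sep="\t", index=False)
    pd.DataFrame(
        [(s, i, p) for (s, i), p in sorted(universe.xrefs.entries.items())],
        columns=["source", "id", "primary"],
    ).to_csv(paths["xrefs"], sep="\t", index=False)
    pd.DataFrame(sorted(universe.known_compounds.items()),
                 columns=["structure_key", "primary"]).to_csv(
        paths["known"], sep="\t", index=False)
    ref = universe.reference
    with open(paths["reference"], "w") as fh:
        json.dump({
            "model_metabolite_keys": sorted(ref.model_metabolite_keys),
            "model_reactions": [
                {"pair": sorted(pair),
                 "enzymes": [{"ec": list(e.ec_numbers), "genes": list(e.genes)}
                             for e in enzymes]}
                for pair, enzymes in sorted(
                    ref.model_reactions.items(), key=lambda kv: sorted(kv[0]))
            ],
            "organism_pairs": sorted(sorted(p) for p in ref.organism_pairs),
            "other_organism_pairs": sorted(
                sorted(p) for p in ref.other_organism_pairs),
        }, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["cofactors"].write_text(
        "".join(f"{c}\n" for c in universe.cofactor_ids))
    pd.DataFrame([
        {
            "substrate_id": t.substrate_id, "substrate_key": t.substrate_key,
            "product_key": t.product_key, "primary": t.product_primary_id,
            "source_reaction": t.source_reaction_id,
            "direction": t.direction, "category": t.category,
        }
        for t in universe.planted
    ]).to_csv(paths["planted"], sep="\t", index=False)
    return paths
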