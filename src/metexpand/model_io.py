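"""Reading and writing metabolic models and concentration tables.

Models are read from BiGG-style JSON or an SBML Level-3 core subset
through cobrapy and adapted into a light species-level view: compartment
tags are stripped so that one chemical species with several compartment
instances appears once (the promiscuity analysis reasons at the
chemical-species level).  Structures come from a sidecar file — an SDF
whose record titles are species ids, or a two-column ``id<TAB>SMILES``
table — and metabolites without a structure stay in the model (their
declared formula still serves balance lookups) but are excluded from
operator extraction and application.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import pandas as pd

from . import chem
from .chem import ElementFormula, MolecularGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ModelError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ConcentrationTable",
    "SubstratePools",
    "load_model",
    "save_model",
    "load_structures",
    "select_substrate_pool",
    "substrate_pools",
]


class ModelError(ValueError):
    pass


@dataclass
class Metabolite:
    """One chemical species (compartment instances merged)."""

    id: str
    name: str = ""
    compartments: tuple[str, ...] = ()
    instance_ids: dict[str, str] = field(default_factory=dict)  # compartment -> raw id
    formula: str | None = None
    charge: int | None = None
    external_ids: dict[str, str] = field(default_factory=dict)
    structure: MolecularGraph | None = None

    @property
    def has_structure(self) -> bool:
        return self.structure is not None

    def element_formula(self) -> ElementFormula | None:
        """Formula from the structure when present, else the declared one."""
        if self.structure is not None:
            return chem.formula_of(self.structure)
        if self.formula:
            return ElementFormula.from_string(self.formula, self.charge or 0)
        return None


@dataclass
class Reaction:
    id: str
    name: str = ""
    ec_numbers: tuple[str, ...] = ()
    genes: tuple[str, ...] = ()
    kegg_ids: tuple[str, ...] = ()
    stoichiometry: dict[str, float] = field(default_factory=dict)  # species id -> coeff
    raw_stoichiometry: dict[str, float] = field(default_factory=dict)  # raw id -> coeff
    reversible: bool = True
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gene_reaction_rule: str = ""

    @property
    def substrates(self) -> list[str]:
        return sorted(s for s, c in self.stoichiometry.items() if c < 0)

    @property
    def products(self) -> list[str]:
        return sorted(s for s, c in self.stoichiometry.items() if c > 0)


@dataclass
class MetabolicModel:
    id: str
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    genes: tuple[str, ...] = ()

    def validate(self) -> None:
        for rxn in self.reactions:
            for sp in rxn.stoichiometry:
                if sp not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id!r} references unknown metabolite {sp!r}"
                    )

    def structure_bearing(self) -> set[str]:
        return {mid for mid, m in self.metabolites.items() if m.has_structure}


def _species_id(raw_id: str, compartment: str | None) -> str:
    if compartment and raw_id.endswith(f"_{compartment}"):
        return raw_id[: -(len(compartment) + 1)]
    return raw_id


def _as_tuple(value) -> tuple[str, ...]:
    if value is None:
        return ()
    if isinstance(value, str):
        return (value,)
    return tuple(str(v) for v in value)


def _validate_bigg_json(path: Path) -> None:
    with open(path) as fh:
        raw = json.load(fh)
    met_ids = {m["id"] for m in raw.get("metabolites", [])}
    for rxn in raw.get("reactions", []):
        for mid in rxn.get("metabolites", {}):
            if mid not in met_ids:
                raise ModelError(
                    f"reaction {rxn.get('id')!r} references unknown metabolite {mid!r}"
                )


def load_model(
    path: str | Path,
    format: str = "bigg-json",
    structures: str | Path | None = None,
) -> MetabolicModel:
    """Load a metabolic model and optionally attach sidecar structures.

    ``format`` is ``"bigg-json"`` or ``"sbml"``.  Reversibility follows the
    flux bounds (reactions are reversible unless the bounds say otherwise).
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bigg-json":
        _validate_bigg_json(path)
        cmodel = cobra.io.load_json_model(str(path))
    elif format == "sbml":
        cmodel = cobra.io.read_sbml_model(str(path))
    else:
        raise ValueError(f"unknown model format: {format!r}")

    metabolites: dict[str, Metabolite] = {}
    for cm in cmodel.metabolites:
        sp = _species_id(cm.id, cm.compartment)
        met = metabolites.get(sp)
        if met is None:
            ann = {
                k: (v[0] if isinstance(v, list) and v else v)
                for k, v in (cm.annotation or {}).items()
            }
            met = Metabolite(
                id=sp,
                name=cm.name or sp,
                formula=cm.formula or None,
                charge=int(cm.charge) if cm.charge is not None else None,
                external_ids={k: str(v) for k, v in ann.items()},
            )
            metabolites[sp] = met
        comp = cm.compartment or ""
        if comp not in met.compartments:
            met.compartments = tuple(sorted({*met.compartments, comp}))
        met.instance_ids[comp] = cm.id

    reactions = []
    for cr in cmodel.reactions:
        stoich: dict[str, float] = {}
        raw: dict[str, float] = {}
        for cm, coeff in cr.metabolites.items():
            sp = _species_id(cm.id, cm.compartment)
            stoich[sp] = stoich.get(sp, 0.0) + float(coeff)
            raw[cm.id] = float(coeff)
        stoich = {sp: c for sp, c in stoich.items() if c}
        ann = cr.annotation or {}
        reactions.append(
            Reaction(
                id=cr.id,
                name=cr.name or cr.id,
                ec_numbers=_as_tuple(ann.get("ec-code")),
                genes=tuple(sorted(g.id for g in cr.genes)),
                kegg_ids=_as_tuple(ann.get("kegg.reaction")),
                stoichiometry=stoich,
                raw_stoichiometry=raw,
                reversible=cr.lower_bound < 0 < cr.upper_bound,
                lower_bound=float(cr.lower_bound),
                upper_bound=float(cr.upper_bound),
                gene_reaction_rule=cr.gene_reaction_rule or "",
            )
        )

    model = MetabolicModel(
        id=cmodel.id or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        genes=tuple(sorted(g.id for g in cmodel.genes)),
    )
    model.validate()
    if structures is not None:
        attach_structures(model, load_structures(structures))
    return model


def load_structures(path: str | Path) -> dict[str, MolecularGraph]:
    """Read a structure sidecar: ``.sdf`` (record title = species id) or a
    two-column ``id<TAB>SMILES`` table (``.tsv``/``.smi``)."""
    from rdkit import Chem as RDChem

    path = Path(path)
    out: dict[str, MolecularGraph] = {}
    if path.suffix.lower() == ".sdf":
        supplier = RDChem.SDMolSupplier(str(path), removeHs=True)
        for mol in supplier:
            if mol is None:
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
            if name:
                out[name.strip()] = chem.from_rdkit(mol)
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["id", "smiles"], dtype=str)
        for _, row in df.iterrows():
            if pd.isna(row["smiles"]) or not str(row["smiles"]).strip():
                continue
            out[str(row["id"]).strip()] = chem.parse_structure(str(row["smiles"]).strip())
    return out


def attach_structures(model: MetabolicModel, structures: Mapping[str, MolecularGraph]) -> None:
    missing = []
    for mid, met in model.metabolites.items():
        g = structures.get(mid)
        if g is not None:
            met.structure = g
        else:
            missing.append(mid)
    if missing:
        logger.warning(
            "%d metabolites without structures (excluded from operator "
            "extraction/application): %s",
            len(missing), ", ".join(sorted(missing)[:10]),
        )


def save_model(model: MetabolicModel, path: str | Path) -> None:
    """Serialise to BiGG-style JSON (via cobrapy's schema)."""
    import cobra
    import cobra.io

    cmodel = cobra.Model(model.id)
    comp_mets = {}
    for met in model.metabolites.values():
        for comp, raw_id in (met.instance_ids or {"c": f"{met.id}_c"}).items():
            cm = cobra.Metabolite(
                raw_id, name=met.name, compartment=comp or "c",
                formula=met.formula, charge=met.charge,
            )
            if met.external_ids:
                cm.annotation = dict(met.external_ids)
            comp_mets[raw_id] = cm
    cmodel.add_metabolites(list(comp_mets.values()))
    crxns = []
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id, name=rxn.name,
                            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for rxn, cr in zip(model.reactions, crxns):
        cr.add_metabolites({comp_mets[rid]: c for rid, c in rxn.raw_stoichiometry.items()})
        cr.gene_reaction_rule = rxn.gene_reaction_rule or " or ".join(rxn.genes)
        ann = {}
        if rxn.ec_numbers:
            ann["ec-code"] = list(rxn.ec_numbers)
        if rxn.kegg_ids:
            ann["kegg.reaction"] = list(rxn.kegg_ids)
        if ann:
            cr.annotation = ann
    cobra.io.save_json_model(cmodel, str(path))


class ConcentrationTable:
    """Metabolite concentrations in µM (one row per species, non-negative)."""

    def __init__(self, values: Mapping[str, float]):
        for mid, v in values.items():
            if v < 0 or math.isnan(v):
                raise ModelError(f"negative or invalid concentration for {mid!r}")
        self.values = dict(values)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConcentrationTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        if list(df.columns[:2]) != ["metabolite_id", "concentration_uM"]:
            raise ModelError(
                "concentration table must have header "
                "'metabolite_id<TAB>concentration_uM'"
            )
        ids = df["metabolite_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ModelError(f"duplicate concentration row for {dup!r}")
        return cls(dict(zip(ids, df["concentration_uM"].astype(float))))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"metabolite_id": list(self.values), "concentration_uM": list(self.values.values())}
        ).to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.values)


class SubstratePools(NamedTuple):
    high: set[str]
    remainder: set[str]


def substrate_pools(
    model: MetabolicModel, conc: ConcentrationTable, threshold_uM: float
) -> SubstratePools:
    """Split structure-bearing species into the high-concentration pool
    (strictly above the threshold) and the remainder.

    Metabolites absent from the table land in the remainder pool; the two
    pools partition the structure-bearing species.
    """
    if threshold_uM < 0:
        raise ValueError("threshold_uM must be non-negative")
    bearing = model.structure_bearing()
    high = {
        mid for mid in bearing
        if mid in conc.values and conc.values[mid] > threshold_uM
    }
    return SubstratePools(high=high, remainder=bearing - high)


def select_substrate_pool(
    model: MetabolicModel, conc: ConcentrationTable, threshold_uM: float
) -> set[str]:
    """Species with concentration strictly greater than ``threshold_uM``."""
    return substrate_pools(model, conc, threshold_uM).high
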