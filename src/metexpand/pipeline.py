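"""End-to-end orchestration: operators → derivatives → matches → curation.

``run_pipeline`` executes the three-step workflow on in-memory objects
and returns a :class:`PipelineResult`; ``write_reports`` serialises the
result as diff-stable TSV/JSON artifacts (sorted, no timestamps), so
repeat runs over identical inputs produce byte-identical reports.

Stage counts are conserved: every non-self derivative is either matched
or unmatched; every matched candidate is either discarded (with a
reason) or classified into exactly one category.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import chem
from .chem import ElementFormula
from .curation import (CandidateReaction, CurationReport, CuratedReaction,
                       ReferenceIndex, check_balance, complete_reaction,
                       summarize)
from .derivatize import PredictedDerivative, enumerate_derivatives
from .matcher import MetaboliteRecord, XrefTable, match_derivatives
from .model_io import ConcentrationTable, MetabolicModel, substrate_pools
from .rdm import OperatorTable, build_operator_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "run_universe",
           "write_reports", "candidates_from_matches"]


@dataclass
class PipelineResult:
    operators: OperatorTable
    pool: set[str]
    derivatives: list[PredictedDerivative]        # non-self predictions
    self_transformations: int
    matches: list[tuple[PredictedDerivative, str]]
    candidates: list[CandidateReaction]
    curated: list[tuple[CandidateReaction, CuratedReaction, bool]]
    report: CurationReport

    def summary(self) -> dict:
        n_matched = len({
            (c.substrate_id, c.product_key, c.kegg_reaction, c.direction)
            for c in self.candidates
        })
        counts = {
            "operators_entries": self.operators.n_entries,
            "operators_merged": len(self.operators),
            "pool_size": len(self.pool),
            "derivatives": len(self.derivatives),
            "self_transformations": self.self_transformations,
            "matched": n_matched,
            "unmatched": len(self.derivatives) - n_matched,
            "discarded": dict(sorted(self.report.discards.items())),
            "kept": self.report.n_kept,
            "categories": dict(sorted(self.report.counts.items())),
            "new_metabolites": self.report.new_metabolites,
            "balanced_reactions": sum(1 for _, _, ok in self.curated if ok),
        }
        return counts


def _template_couples(
    prov, origin, model: MetabolicModel
) -> tuple[tuple[tuple[str, float], ...], tuple[tuple[str, float], ...], bool]:
    """The template reaction's cofactor couple: all participants except
    the native main pair, oriented by the operator direction."""
    rxn = next((r for r in model.reactions if r.id == prov.reaction_id), None)
    if rxn is None:
        return (), (), False
    subs = {m: -c for m, c in rxn.stoichiometry.items() if c < 0}
    prods = {m: c for m, c in rxn.stoichiometry.items() if c > 0}
    if prov.direction == "reverse":
        subs, prods = prods, subs
    subs.pop(origin.substrate_id, None)
    prods.pop(origin.product_id, None)
    return tuple(sorted(subs.items())), tuple(sorted(prods.items())), True


def candidates_from_matches(
    matches: Sequence[tuple[PredictedDerivative, str]],
    model: MetabolicModel,
    table: OperatorTable | None = None,
    cofactor_ids: Iterable[str] = (),
    feasibility: Mapping[tuple[str, str], bool] | None = None,
) -> list[CandidateReaction]:
    """Turn matched derivatives into curation candidates, copying the
    template reaction's cofactor couple from the operator's provenance.

    ``feasibility`` optionally overrides the per-candidate feasibility
    flag (keyed by (substrate id, product key)); the default is feasible,
    standing in for the manual chemical review.
    """
    cof = set(cofactor_ids)
    feas = dict(feasibility or {})
    origin_by_prov = {}
    if table is not None:
        for op in table.operators:
            origin_by_prov.update(op.sources)
    out: dict[tuple, CandidateReaction] = {}
    for deriv, db_id in matches:
        dkey = (deriv.parent_id, deriv.product_key,
                deriv.provenance.reaction_id, deriv.provenance.direction)
        if dkey in out:
            continue
        prov = deriv.provenance
        origin = origin_by_prov.get(prov)
        if origin is not None:
            co_subs, co_prods, has_template = _template_couples(
                prov, origin, model)
        else:
            co_subs, co_prods, has_template = (), (), False
        out[dkey] = CandidateReaction(
            substrate_id=deriv.parent_id,
            substrate_key=deriv.parent_key,
            product_id=db_id,
            product_key=deriv.product_key,
            ec_numbers=prov.ec_numbers,
            genes=prov.genes,
            kegg_reaction=prov.kegg_reaction,
            direction=prov.direction,
            feasible=feas.get((deriv.parent_id, deriv.product_key), True),
            multi_center=False,
            substrate_is_cofactor=deriv.parent_id in cof,
            co_substrates=co_subs,
            co_products=co_prods,
            has_template=has_template,
        )
    return [out[k] for k in sorted(out)]


def run_pipeline(
    model: MetabolicModel,
    concentrations: ConcentrationTable,
    metabolome: Sequence[MetaboliteRecord],
    xrefs: XrefTable,
    reference: ReferenceIndex,
    known_compounds: Mapping[str, str] | None = None,
    cofactor_ids: Iterable[str] = (),
    threshold_uM: float = 1.0,
    include_remainder_pool: bool = False,
    feasibility: Mapping[tuple[str, str], bool] | None = None,
    tolerate_h: bool = False,
) -> PipelineResult:
    """Run the three-step workflow and return all stage artifacts."""
    cof = tuple(sorted(set(cofactor_ids)))
    table = build_operator_table(model, cofactor_ids=cof)

    pools = substrate_pools(model, concentrations, threshold_uM)
    pool = set(pools.high) - set(cof)
    if include_remainder_pool:
        pool |= pools.remainder - set(cof)
    logger.info("substrate pool: %d high-concentration metabolites "
                "(threshold %g uM)", len(pools.high), threshold_uM)

    all_derivs = enumerate_derivatives(table, pool, model, known_compounds)
    derivs = [d for d in all_derivs if not d.self_transformation]
    n_self = len(all_derivs) - len(derivs)

    matches = match_derivatives(derivs, list(metabolome), xrefs)

    candidates = candidates_from_matches(
        matches, model, table=table, cofactor_ids=cof, feasibility=feasibility)

    report = summarize(candidates, reference)

    formulas: dict[str, ElementFormula] = {}
    for mid, met in model.metabolites.items():
        f = met.element_formula()
        if f is not None:
            formulas[mid] = f
    for deriv, db_id in matches:
        formulas.setdefault(db_id, chem.formula_of(deriv.product))

    curated = []
    for c, label in report.labels:
        if label.is_discard:
            continue
        r = complete_reaction(c)
        try:
            bal = check_balance(r, formulas, tolerate_h=tolerate_h)
            ok = bal.balanced
        except KeyError:
            ok = False
        curated.append((c, r, ok))

    return PipelineResult(
        operators=table,
        pool=pool,
        derivatives=derivs,
        self_transformations=n_self,
        matches=matches,
        candidates=candidates,
        curated=curated,
        report=report,
    )


def write_reports(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write all stage reports; sorted and timestamp-free, so repeated
    runs are byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    ops_rows = []
    for op in sorted(result.operators.operators,
                     key=lambda o: (o.key, o.value,
                                    tuple((p.reaction_id, p.direction)
                                          for p in o.provenance))):
        for prov in op.provenance:
            ops_rows.append({
                "ec": ";".join(prov.ec_numbers),
                "genes": ";".join(prov.genes),
                "kegg_reaction": prov.kegg_reaction,
                "reaction": prov.reaction_id,
                "direction": prov.direction,
                "key_r": op.key[0],
                "key_m": ";".join(op.key[1]),
                "key_d": ";".join(op.key[2]),
                "value_r": op.value[0],
                "value_d": ";".join(op.value[1]),
            })
    paths["operators"] = outdir / "operators.tsv"
    pd.DataFrame(ops_rows).to_csv(paths["operators"], sep="\t", index=False)

    paths["operators_json"] = outdir / "operators.json"
    with open(paths["operators_json"], "w") as fh:
        json.dump([
            {
                "key": {"r": op.key[0], "m": list(op.key[1]),
                        "d": list(op.key[2])},
                "value": {"r": op.value[0], "d": list(op.value[1])},
                "graph_edit": {
                    "rebonds": [vars(rb) for rb in op.edit.rebonds],
                    "deletes": [
                        {"atoms": list(s.atoms), "bonds": list(s.bonds),
                         "attach": list(s.attach)}
                        for s in op.edit.deletes],
                    "attaches": [
                        {"atoms": list(s.atoms), "bonds": list(s.bonds),
                         "attach": list(s.attach)}
                        for s in op.edit.attaches],
                    "r_charge_delta": op.edit.r_charge_delta,
                },
                "provenance": [
                    {"ec": list(p.ec_numbers), "genes": list(p.genes),
                     "kegg_reaction": p.kegg_reaction,
                     "reaction": p.reaction_id, "direction": p.direction}
                    for p in op.provenance],
            }
            for op in sorted(
                result.operators.operators,
                key=lambda o: (o.key, o.value,
                               tuple((p.reaction_id, p.direction)
                                     for p in o.provenance)))
        ], fh, indent=1, sort_keys=True)
        fh.write("\n")

    paths["derivatives"] = outdir / "derivatives.tsv"
    pd.DataFrame([
        {
            "parent": d.parent_id,
            "ec": ";".join(d.provenance.ec_numbers),
            "gene": ";".join(d.provenance.genes),
            "kegg_reaction": d.provenance.kegg_reaction,
            "direction": d.provenance.direction,
            "product_key": d.product_key,
            "known_id": d.known_id or "",
            "already_in_model": int(d.already_in_model),
        }
        for d in result.derivatives
    ]).to_csv(paths["derivatives"], sep="\t", index=False)

    paths["matches"] = outdir / "matches.tsv"
    pd.DataFrame([
        {"parent": d.parent_id, "product_key": d.product_key,
         "record": db_id, "known_id": d.known_id or ""}
        for d, db_id in result.matches
    ]).to_csv(paths["matches"], sep="\t", index=False)

    label_by_candidate = {id(c): lab for c, lab in result.report.labels}
    paths["categories"] = outdir / "categories.tsv"
    rows = []
    for c, lab in result.report.labels:
        rows.append({
            "category": lab.category,
            "reason": lab.reason or "",
            "ec": ";".join(c.ec_numbers),
            "genes": ";".join(c.genes),
            "substrate": c.substrate_id,
            "product": c.product_id,
            "direction": c.direction,
        })
    rows.sort(key=lambda r: (r["category"], r["ec"], r["substrate"],
                             r["product"]))
    pd.DataFrame(rows).to_csv(paths["categories"], sep="\t", index=False)

    paths["curated"] = outdir / "curated_reactions.tsv"
    crows = []
    for c, r, ok in sorted(result.curated,
                           key=lambda t: (t[0].ec_numbers, t[0].substrate_id,
                                          t[0].product_id)):
        crows.append({
            "ec": ";".join(c.ec_numbers),
            "genes": ";".join(c.genes),
            "equation": r.equation(),
            "balanced": int(ok),
        })
    pd.DataFrame(crows).to_csv(paths["curated"], sep="\t", index=False)

    paths["summary"] = outdir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def run_universe(universe) -> PipelineResult:
    """Run the pipeline on a generated :class:`~metexpand.fixtures.toy.
    ToyUniverse` with its own settings (convenience wrapper)."""
    return run_pipeline(
        model=universe.model,
        concentrations=universe.concentrations,
        metabolome=universe.metabolome,
        xrefs=universe.xrefs,
        reference=universe.reference,
        known_compounds=universe.known_compounds,
        cofactor_ids=universe.cofactor_ids,
        threshold_uM=universe.threshold_uM,
    )
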