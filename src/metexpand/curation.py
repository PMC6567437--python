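"""Curation of verified predictions into balanced, classified reactions.

Verified substrate→derivative transformations pass three discard filters
(infeasible, cofactor substrate, multi-centre rule), are completed into
stoichiometric reactions by copying the cofactor couple of the enzyme's
template reaction, checked for elemental balance, and classified into
four evidence categories with a decision tree:

* **C1** — the transformation is a parallel route: the same substrate/
  product pair is catalysed in the model (or documented elsewhere) by a
  different enzyme.  A same-enzyme hit is discarded as already present.
* **C2** — the transformation is absent from the model but documented
  for the organism in reference databases (a curation gap).
* **C3** — documented only in other organisms.
* **C4** — not catalogued anywhere.

Reference lookups are direction-agnostic (reactions are assumed
reversible unless stated otherwise), so a transformation is the
unordered (substrate key, product key) pair.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .chem import ElementFormula

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryLabel",
    "C1", "C2", "C3", "C4",
    "discard",
    "EnzymeRef",
    "CandidateReaction",
    "CuratedReaction",
    "BalanceReport",
    "ReferenceIndex",
    "apply_discard_filters",
    "complete_reaction",
    "check_balance",
    "classify",
    "summarize",
    "CurationReport",
]


@dataclass(frozen=True)
class CategoryLabel:
    category: str  # "C1".."C4" or "DISCARD"
    reason: str | None = None

    @property
    def is_discard(self) -> bool:
        return self.category == "DISCARD"

    def __str__(self) -> str:
        return self.category if not self.reason else f"{self.category}({self.reason})"


C1 = CategoryLabel("C1")
C2 = CategoryLabel("C2")
C3 = CategoryLabel("C3")
C4 = CategoryLabel("C4")
CATEGORIES = ("C1", "C2", "C3", "C4")


def discard(reason: str) -> CategoryLabel:
    return CategoryLabel("DISCARD", reason)


@dataclass(frozen=True)
class EnzymeRef:
    ec_numbers: tuple[str, ...] = ()
    genes: tuple[str, ...] = ()

    def same_enzyme(self, other: "EnzymeRef") -> bool:
        """Gene-set comparison, falling back to EC numbers when either
        side lacks gene annotations."""
        if self.genes and other.genes:
            return bool(set(self.genes) & set(other.genes))
        return bool(set(self.ec_numbers) & set(other.ec_numbers))


@dataclass(frozen=True)
class CandidateReaction:
    """A verified predicted transformation awaiting curation.

    ``feasible`` stands in for the manual chemical-feasibility judgment
    (defaults to feasible); ``parallel_route`` optionally records a
    documented parallel route by a different enzyme that is not part of
    the model reaction set (a curator-supplied assertion).
    """

    substrate_id: str
    substrate_key: str
    product_id: str
    product_key: str
    ec_numbers: tuple[str, ...] = ()
    genes: tuple[str, ...] = ()
    kegg_reaction: str = ""
    direction: str = "forward"
    feasible: bool = True
    multi_center: bool = False
    substrate_is_cofactor: bool = False
    parallel_route: tuple[EnzymeRef, ...] = ()
    co_substrates: tuple[tuple[str, float], ...] = ()
    co_products: tuple[tuple[str, float], ...] = ()
    has_template: bool = True

    @property
    def enzyme(self) -> EnzymeRef:
        return EnzymeRef(self.ec_numbers, self.genes)

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.substrate_key, self.product_key))


@dataclass
class CuratedReaction:
    stoichiometry: dict[str, float]
    ec_numbers: tuple[str, ...] = ()
    genes: tuple[str, ...] = ()
    reversible: bool = True
    uncompleted: bool = False

    def equation(self) -> str:
        def side(sign: int) -> str:
            parts = []
            for mid in sorted(self.stoichiometry):
                coeff = self.stoichiometry[mid]
                if sign * coeff > 0:
                    c = abs(coeff)
                    parts.append(mid if c == 1 else f"{c:g} {mid}")
            return " + ".join(parts)
        arrow = "<=>" if self.reversible else "-->"
        return f"{side(-1)} {arrow} {side(+1)}"


@dataclass(frozen=True)
class BalanceReport:
    element_deltas: Mapping[str, float]   # product side minus substrate side
    h_delta: float
    charge_delta: float
    balanced: bool                        # all heavy-atom deltas zero
    adjustments: tuple[tuple[str, float], ...] = ()

    @property
    def fully_balanced(self) -> bool:
        return self.balanced and not self.h_delta and not self.charge_delta


@dataclass
class ReferenceIndex:
    """Key-normalised reference sets for the decision tree."""

    model_metabolite_keys: frozenset[str] = frozenset()
    model_reactions: Mapping[frozenset[str], tuple[EnzymeRef, ...]] = \
        field(default_factory=dict)
    organism_pairs: frozenset[frozenset[str]] = frozenset()
    other_organism_pairs: frozenset[frozenset[str]] = frozenset()


def apply_discard_filters(c: CandidateReaction) -> CategoryLabel | None:
    """First matching discard reason in fixed order (infeasible, cofactor
    substrate, multi-centre), or ``None`` to keep the candidate."""
    if not c.feasible:
        return discard("infeasible")
    if c.substrate_is_cofactor:
        return discard("cofactor-substrate")
    if c.multi_center:
        return discard("multi-center")
    return None


def complete_reaction(c: CandidateReaction) -> CuratedReaction:
    """Build the stoichiometric reaction by copying the template
    reaction's cofactor couple onto the substrate/product pair."""
    stoich: dict[str, float] = {c.substrate_id: -1.0, c.product_id: +1.0}
    for mid, coeff in c.co_substrates:
        stoich[mid] = stoich.get(mid, 0.0) - coeff
    for mid, coeff in c.co_products:
        stoich[mid] = stoich.get(mid, 0.0) + coeff
    uncompleted = not c.has_template
    if uncompleted:
        logger.warning("candidate %s->%s has no template reaction; emitted "
                       "without cofactors", c.substrate_id, c.product_id)
    return CuratedReaction(
        stoichiometry={k: v for k, v in stoich.items() if v},
        ec_numbers=c.ec_numbers,
        genes=c.genes,
        uncompleted=uncompleted,
    )


def check_balance(
    r: CuratedReaction,
    formulas: Mapping[str, ElementFormula],
    tolerate_h: bool = False,
) -> BalanceReport:
    """Per-element balance of a curated reaction.

    Deltas are product side minus substrate side; the reaction is
    balanced iff every heavy-atom delta is zero.  Hydrogen and charge
    deltas are reported separately; with ``tolerate_h`` they may be
    absorbed by adding protons (and the addition is recorded), but the
    heavy-atom criterion never relaxes.
    """
    total = ElementFormula({}, 0)
    for mid, coeff in r.stoichiometry.items():
        f = formulas.get(mid)
        if f is None:
            raise KeyError(f"no formula for metabolite {mid!r}")
        total = total + f.scaled(coeff)
    heavy = {el: d for el, d in total.heavy().items() if d}
    h_delta = total.counts.get("H", 0.0)
    charge_delta = total.charge
    adjustments: tuple[tuple[str, float], ...] = ()
    if tolerate_h and not heavy and h_delta and h_delta == charge_delta:
        adjustments = (("H+", -h_delta),)
        logger.info("balance: absorbing %+g H+ into %s", -h_delta, r.equation())
        h_delta = 0.0
        charge_delta = 0.0
    return BalanceReport(
        element_deltas=heavy,
        h_delta=h_delta,
        charge_delta=charge_delta,
        balanced=not heavy,
        adjustments=adjustments,
    )


def classify(c: CandidateReaction, ref: ReferenceIndex) -> CategoryLabel:
    """Decision-tree classification of a kept candidate.

    Root test: is the transformation (unordered substrate/product pair)
    represented in the model?  If so, a different catalysing enzyme makes
    it a parallel route (C1) and the same enzyme a discard; a documented
    parallel route asserted on the candidate also lands in C1.  Otherwise
    the organism reference set decides C2, other organisms C3, and no
    record anywhere C4.
    """
    entries = ref.model_reactions.get(c.pair, ())
    if entries:
        if any(c.enzyme.same_enzyme(e) for e in entries):
            return discard("already-in-model")
        return C1
    if c.parallel_route and not any(
        c.enzyme.same_enzyme(e) for e in c.parallel_route
    ):
        return C1
    if c.pair in ref.organism_pairs:
        return C2
    if c.pair in ref.other_organism_pairs:
        return C3
    return C4


@dataclass
class CurationReport:
    labels: list[tuple[CandidateReaction, CategoryLabel]]
    counts: dict[str, int]
    discards: dict[str, int]
    new_metabolites: list[str]

    @property
    def n_kept(self) -> int:
        return sum(self.counts.values())


def summarize(
    candidates: Sequence[CandidateReaction], ref: ReferenceIndex
) -> CurationReport:
    """Run filters + classification over all candidates and aggregate.

    New-to-model metabolites are the distinct product keys of C2/C3/C4
    reactions absent from the model metabolite set (C1 adds none — its
    products already exist in the model or arise via parallel routes).
    """
    labels: list[tuple[CandidateReaction, CategoryLabel]] = []
    counts = {cat: 0 for cat in CATEGORIES}
    discards: dict[str, int] = {}
    new_mets: dict[str, str] = {}
    for c in candidates:
        label = apply_discard_filters(c)
        if label is None:
            label = classify(c, ref)
        labels.append((c, label))
        if label.is_discard:
            discards[label.reason or ""] = discards.get(label.reason or "", 0) + 1
        else:
            counts[label.category] += 1
            if label.category in ("C2", "C3", "C4") and \
                    c.product_key not in ref.model_metabolite_keys:
                new_mets[c.product_key] = c.product_id
    return CurationReport(
        labels=labels,
        counts=counts,
        discards=discards,
        new_metabolites=sorted(new_mets.values()),
    )


# ---------------------------------------------------------------------------
# table I/O (candidates as TSV, reference index as JSON)
# ---------------------------------------------------------------------------

def _pack_couple(couple: tuple[tuple[str, float], ...]) -> str:
    return ";".join(f"{m}:{c:g}" for m, c in couple)


def _unpack_couple(text: str) -> tuple[tuple[str, float], ...]:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        mid, _, coeff = part.rpartition(":")
        out.append((mid, float(coeff)))
    return tuple(out)


def write_candidates_tsv(candidates: Sequence[CandidateReaction],
                         path: str | Path) -> None:
    pd.DataFrame([
        {
            "substrate_id": c.substrate_id,
            "substrate_key": c.substrate_key,
            "product_id": c.product_id,
            "product_key": c.product_key,
            "ec": ";".join(c.ec_numbers),
            "genes": ";".join(c.genes),
            "kegg_reaction": c.kegg_reaction,
            "direction": c.direction,
            "feasible": int(c.feasible),
            "multi_center": int(c.multi_center),
            "substrate_is_cofactor": int(c.substrate_is_cofactor),
            "co_substrates": _pack_couple(c.co_substrates),
            "co_products": _pack_couple(c.co_products),
            "parallel_route": "|".join(
                ";".join(e.ec_numbers) + "/" + ";".join(e.genes)
                for e in c.parallel_route
            ),
        }
        for c in candidates
    ]).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path) -> list[CandidateReaction]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        parallel = tuple(
            EnzymeRef(
                tuple(x for x in part.split("/")[0].split(";") if x),
                tuple(x for x in part.split("/")[1].split(";") if x),
            )
            for part in row["parallel_route"].split("|") if part
        )
        out.append(CandidateReaction(
            substrate_id=row["substrate_id"],
            substrate_key=row["substrate_key"],
            product_id=row["product_id"],
            product_key=row["product_key"],
            ec_numbers=tuple(x for x in row["ec"].split(";") if x),
            genes=tuple(x for x in row["genes"].split(";") if x),
            kegg_reaction=row["kegg_reaction"],
            direction=row["direction"] or "forward",
            feasible=row["feasible"] != "0",
            multi_center=row["multi_center"] == "1",
            substrate_is_cofactor=row["substrate_is_cofactor"] == "1",
            co_substrates=_unpack_couple(row["co_substrates"]),
            co_products=_unpack_couple(row["co_products"]),
            parallel_route=parallel,
        ))
    return out


def write_reference_index(ref: ReferenceIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "model_metabolite_keys": sorted(ref.model_metabolite_keys),
            "model_reactions": [
                {"pair": sorted(pair),
                 "enzymes": [{"ec": list(e.ec_numbers), "genes": list(e.genes)}
                             for e in enzymes]}
                for pair, enzymes in sorted(ref.model_reactions.items(),
                                            key=lambda kv: sorted(kv[0]))
            ],
            "organism_pairs": sorted(sorted(p) for p in ref.organism_pairs),
            "other_organism_pairs": sorted(
                sorted(p) for p in ref.other_organism_pairs),
        }, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_reference_index(path: str | Path) -> ReferenceIndex:
    with open(path) as fh:
        raw = json.load(fh)
    return ReferenceIndex(
        model_metabolite_keys=frozenset(raw.get("model_metabolite_keys", ())),
        model_reactions={
            frozenset(entry["pair"]): tuple(
                EnzymeRef(tuple(e.get("ec", ())), tuple(e.get("genes", ())))
                for e in entry["enzymes"]
            )
            for entry in raw.get("model_reactions", ())
        },
        organism_pairs=frozenset(
            frozenset(p) for p in raw.get("organism_pairs", ())),
        other_organism_pairs=frozenset(
            frozenset(p) for p in raw.get("other_organism_pairs", ())),
    )
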