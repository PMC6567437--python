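"""Metabolite identity reconciliation and derivative matching.

Metabolomics records (ECMDB-style exports) carry a declared primary
compound id plus cross-references (InChIKey, KEGG, CAS, ChEBI, BioCyc).
Each cross-reference is resolved to a primary id through an offline
lookup table and the record's identity is decided by majority vote; a
record without a strict majority stays unresolved and is excluded from
matching.  Predicted derivatives are then matched against the reconciled
records by primary id, falling back to canonical structure keys when the
record provides a structure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .derivatize import PredictedDerivative

__all__ = [
    "XREF_SOURCES",
    "MetaboliteRecord",
    "XrefTable",
    "ReconcileResult",
    "reconcile_primary_id",
    "reconcile_records",
    "match_derivatives",
    "load_metabolome_tsv",
    "load_xref_table_tsv",
]

XREF_SOURCES = ("inchikey", "kegg", "cas", "chebi", "biocyc")


@dataclass(frozen=True)
class MetaboliteRecord:
    db_id: str
    name: str = ""
    formula: str = ""
    declared_primary_id: str | None = None
    xrefs: Mapping[str, str] = field(default_factory=dict)
    structure_key: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.xrefs) - set(XREF_SOURCES)
        if unknown:
            raise ValueError(f"unknown xref sources {sorted(unknown)} "
                             f"on record {self.db_id!r}")


class XrefTable:
    """Deterministic offline (source, id) → primary-id lookup."""

    def __init__(self, entries: Mapping[tuple[str, str], str]):
        self.entries = dict(entries)

    def resolve(self, source: str, xref_id: str) -> str | None:
        return self.entries.get((source, xref_id))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ReconcileResult:
    primary_id: str | None
    consistent: bool
    votes: tuple[str, ...] = ()

    @property
    def resolved(self) -> bool:
        return self.primary_id is not None


def reconcile_primary_id(rec: MetaboliteRecord, x: XrefTable) -> ReconcileResult:
    """Majority-vote identity reconciliation for one record.

    The ids retrieved through each resolvable cross-reference plus the
    record's declared primary id each cast one vote; the winner needs a
    strict majority (> half of cast votes), otherwise the record is
    unresolved.  The consistency flag is true iff every retrieved id
    agrees with the declared id.  The outcome is independent of
    cross-reference enumeration order.
    """
    retrieved = []
    for source in sorted(rec.xrefs):
        rid = x.resolve(source, rec.xrefs[source])
        if rid is not None:
            retrieved.append(rid)
    votes = list(retrieved)
    if rec.declared_primary_id:
        votes.append(rec.declared_primary_id)
    if not votes:
        return ReconcileResult(None, False, ())
    counts = Counter(votes)
    winner, n = counts.most_common(1)[0]
    primary = winner if n * 2 > len(votes) else None
    consistent = (
        rec.declared_primary_id is not None
        and all(r == rec.declared_primary_id for r in retrieved)
    )
    return ReconcileResult(primary, consistent, tuple(sorted(votes)))


def reconcile_records(
    records: Sequence[MetaboliteRecord], x: XrefTable
) -> dict[str, ReconcileResult]:
    return {rec.db_id: reconcile_primary_id(rec, x) for rec in records}


def match_derivatives(
    derivs: Sequence[PredictedDerivative],
    records: Sequence[MetaboliteRecord],
    x: XrefTable,
) -> list[tuple[PredictedDerivative, str]]:
    """Match predicted derivatives against a metabolomics table.

    A derivative matches a record when its known-compound id equals the
    record's reconciled primary id, or — as a structural fallback — when
    the canonical structure keys are equal.  Records that failed
    reconciliation never match.  Output order is independent of record
    order.
    """
    reconciled = reconcile_records(records, x)
    by_primary: dict[str, list[str]] = {}
    by_key: dict[str, list[str]] = {}
    for rec in records:
        res = reconciled[rec.db_id]
        if not res.resolved:
            continue
        by_primary.setdefault(res.primary_id, []).append(rec.db_id)
        if rec.structure_key:
            by_key.setdefault(rec.structure_key, []).append(rec.db_id)

    matches = []
    for deriv in derivs:
        hits: set[str] = set()
        if deriv.known_id:
            hits.update(by_primary.get(deriv.known_id, ()))
        hits.update(by_key.get(deriv.product_key, ()))
        for db_id in sorted(hits):
            matches.append((deriv, db_id))
    return sorted(matches, key=lambda m: (m[0].sort_key(), m[1]))


def load_metabolome_tsv(path: str | Path) -> list[MetaboliteRecord]:
    """Read an ECMDB-like export: columns id, name, formula, pubchem,
    inchikey, kegg, cas, chebi, biocyc (missing cells empty)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        xrefs = {
            src: row[src].strip()
            for src in XREF_SOURCES
            if src in df.columns and row[src].strip()
        }
        records.append(MetaboliteRecord(
            db_id=row["id"].strip(),
            name=row.get("name", "").strip(),
            formula=row.get("formula", "").strip(),
            declared_primary_id=row.get("pubchem", "").strip() or None,
            xrefs=xrefs,
            structure_key=row.get("structure_key", "").strip() or None,
        ))
    ids = [r.db_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate db_id in metabolome table")
    return records


def load_xref_table_tsv(path: str | Path) -> XrefTable:
    """Read an offline cross-reference table: columns source, id, primary."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    entries = {}
    for _, row in df.iterrows():
        key = (row["source"].strip(), row["id"].strip())
        if key in entries and entries[key] != row["primary"].strip():
            raise ValueError(f"conflicting xref entry for {key}")
        entries[key] = row["primary"].strip()
    return XrefTable(entries)
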