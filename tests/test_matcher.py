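"""Majority-vote identity reconciliation and derivative matching."""

import itertools
from collections import Counter

from metexpand.chem import canonical_key, parse_structure
from metexpand.derivatize import PredictedDerivative
from metexpand.matcher import (MetaboliteRecord, XrefTable,
                               match_derivatives, reconcile_primary_id)
from metexpand.rdm import Provenance


def record(xrefs, declared=None, db_id="M1", structure_key=None):
    return MetaboliteRecord(db_id=db_id, name=db_id,
                            declared_primary_id=declared, xrefs=xrefs,
                            structure_key=structure_key)


class TestReconcile:
    def test_retrieved_majority_overrides_declared(self):
        x = XrefTable({("inchikey", "i"): "P1", ("kegg", "k"): "P1",
                       ("cas", "c"): "P1"})
        res = reconcile_primary_id(
            record({"inchikey": "i", "kegg": "k", "cas": "c"},
                   declared="P2"), x)
        assert res.primary_id == "P1"
        assert not res.consistent

    def test_all_agree(self):
        x = XrefTable({("inchikey", "i"): "P1", ("kegg", "k"): "P1"})
        res = reconcile_primary_id(
            record({"inchikey": "i", "kegg": "k"}, declared="P1"), x)
        assert res.primary_id == "P1"
        assert res.consistent

    def test_declared_id_counts_as_a_vote(self):
        x = XrefTable({("inchikey", "i"): "P1", ("kegg", "k"): "P2"})
        res = reconcile_primary_id(
            record({"inchikey": "i", "kegg": "k"}, declared="P2"), x)
        assert res.primary_id == "P2"  # 2-vs-1 majority

    def test_nothing_resolvable(self):
        res = reconcile_primary_id(record({"kegg": "k"}), XrefTable({}))
        assert res.primary_id is None

    def test_vote_independent_of_source_order(self):
        entries = {("inchikey", "i"): "P1", ("kegg", "k"): "P2",
                   ("cas", "c"): "P1"}
        x = XrefTable(entries)
        r1 = record({"inchikey": "i", "kegg": "k", "cas": "c"}, declared="P2")
        r2 = record(dict(reversed(list(r1.xrefs.items()))), declared="P2")
        assert reconcile_primary_id(r1, x) == reconcile_primary_id(r2, x)

    def test_agrees_with_brute_force_over_all_vote_splits(self):
        """Exhaustive oracle: every assignment of <=4 sources to one of
        three ids, declared id present or absent."""
        sources = ["inchikey", "kegg", "cas", "chebi"]
        ids = ["P1", "P2", "P3"]
        for n in range(len(sources) + 1):
            for assignment in itertools.product(ids, repeat=n):
                for declared in (None, "P1", "P2"):
                    xrefs = {sources[k]: f"x{k}" for k in range(n)}
                    table = XrefTable({
                        (sources[k], f"x{k}"): assignment[k]
                        for k in range(n)
                    })
                    votes = list(assignment) + ([declared] if declared else [])
                    if votes:
                        top, cnt = Counter(votes).most_common(1)[0]
                        expected = top if 2 * cnt > len(votes) else None
                    else:
                        expected = None
                    got = reconcile_primary_id(
                        record(xrefs, declared=declared), table)
                    assert got.primary_id == expected, (assignment, declared)


def make_derivative(parent, smiles, known_id=None):
    g = parse_structure(smiles)
    return PredictedDerivative(
        parent_id=parent, parent_key="pk", site=0,
        product_key=canonical_key(g), product=g,
        provenance=Provenance(("1.1.1.1",), ("g1",), "R1", "RX", "forward"),
        known_id=known_id,
    )


class TestMatchDerivatives:
    def setup_method(self):
        self.x = XrefTable({("kegg", "k1"): "P1", ("kegg", "k2"): "P2",
                            ("inchikey", "i1"): "P1",
                            ("inchikey", "i2"): "P2"})
        self.records = [
            record({"kegg": "k1", "inchikey": "i1"}, declared="P1",
                   db_id="M1"),
            record({"kegg": "k2", "inchikey": "i2"}, declared="P2",
                   db_id="M2"),
        ]
        self.derivs = [
            make_derivative("a", "CCO", known_id="P1"),
            make_derivative("b", "CC=O", known_id="P2"),
            make_derivative("c", "CCC"),
            make_derivative("d", "CCCC"),
            make_derivative("e", "CCCCC"),
        ]

    def test_two_of_five_match(self):
        matches = match_derivatives(self.derivs, self.records, self.x)
        assert {(d.parent_id, m) for d, m in matches} == \
            {("a", "M1"), ("b", "M2")}

    def test_empty_metabolome(self):
        assert match_derivatives(self.derivs, [], self.x) == []

    def test_unreconciled_record_never_matches(self):
        bad = record({"kegg": "k1", "inchikey": "i2"}, declared="P3",
                     db_id="M3")  # three-way split, no majority
        matches = match_derivatives(self.derivs, [bad], self.x)
        assert matches == []

    def test_structure_key_fallback(self):
        key = canonical_key(parse_structure("CCC"))
        rec = record({"kegg": "k1"}, declared="P1", db_id="M9",
                     structure_key=key)
        matches = match_derivatives(self.derivs, [rec], self.x)
        # derivative "c" matches by structure; "a" by its known id (the
        # record reconciles to P1)
        assert {(d.parent_id, m) for d, m in matches} == \
            {("a", "M9"), ("c", "M9")}

    def test_independent_of_record_order(self):
        a = match_derivatives(self.derivs, self.records, self.x)
        b = match_derivatives(self.derivs, list(reversed(self.records)),
                              self.x)
        assert [(d.parent_id, m) for d, m in a] == \
               [(d.parent_id, m) for d, m in b]
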