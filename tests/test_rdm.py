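"""Atom mapping, RDM extraction and the operator table."""

import random

from rdkit import Chem

from metexpand.chem import parse_structure, canonical_key, from_rdkit
from metexpand.derivatize import apply_operator, find_sites
from metexpand.model_io import MetabolicModel, Metabolite, Reaction
from metexpand.rdm import build_operator_table, extract_rdm, map_atoms


def single_pattern(sub_smi, prod_smi):
    s, p = parse_structure(sub_smi), parse_structure(prod_smi)
    pats = extract_rdm(s, p, map_atoms(s, p))
    assert len(pats) == 1
    return s, p, pats[0]


class TestMapAtoms:
    def test_pyruvate_lactate_localises_to_one_centre(self):
        s = parse_structure("CC(=O)C(=O)O")
        p = parse_structure("CC(O)C(=O)O")
        pats = extract_rdm(s, p, map_atoms(s, p))
        assert len(pats) == 1
        assert pats[0].r_atom_index == 1  # the keto carbon

    def test_identical_graphs_map_completely(self):
        g = parse_structure("NC(CCC(=O)O)C(=O)O")
        m = map_atoms(g, g)
        assert m.n_mapped == g.n_atoms
        assert not m.lost and not m.gained

    def test_near_disjoint_molecules(self):
        m = map_atoms(parse_structure("C"), parse_structure("c1ccccc1"))
        assert m.n_mapped <= 1

    def test_mapped_elements_agree(self):
        s = parse_structure("OCC(=O)C(O)C(O)COP(=O)(O)O")
        p = parse_structure("OP(=O)(O)OCC(=O)C(O)C(O)COP(=O)(O)O")
        m = map_atoms(s, p)
        for i, j in m.pairs:
            assert s.atoms[i].element == p.atoms[j].element


class TestExtractRdm:
    def test_oxoglutarate_hydroxyglutarate(self):
        _, _, pat = single_pattern("OC(=O)CCC(=O)C(=O)O",
                                   "OC(=O)CCC(O)C(=O)O")
        assert pat.d_substrate == ("O.dc",)   # carbonyl oxygen leaves
        assert pat.d_product == ("O.h",)      # hydroxyl oxygen arrives
        assert pat.valid

    def test_identical_pair_gives_no_pattern(self):
        g = parse_structure("CCO")
        assert extract_rdm(g, g, map_atoms(g, g)) == []

    def test_two_distant_changes_are_multi_centre(self):
        s = parse_structure("OCCCCCO")
        p = parse_structure("O=CCCCC=O")
        assert len(extract_rdm(s, p, map_atoms(s, p))) == 2

    def test_pattern_key_has_difference_region(self):
        _, _, pat = single_pattern("CCO", "CC=O")
        assert pat.d_substrate or pat.d_product


def reaction_model(reversible=True, pair=("CC(O)CC", "CC(=O)CC"),
                   cofactors=()):
    mets = {}
    for mid, smi in [("sub", pair[0]), ("prod", pair[1]), *cofactors]:
        mets[mid] = Metabolite(id=mid, name=mid,
                               structure=parse_structure(smi))
    stoich = {"sub": -1.0, "prod": 1.0}
    for cid, _ in cofactors:
        stoich.setdefault(cid, -1.0)
    return MetabolicModel(
        id="t", metabolites=mets,
        reactions=[Reaction(id="RX", ec_numbers=("1.1.1.1",), genes=("g1",),
                            kegg_ids=("R00001",), stoichiometry=stoich,
                            reversible=reversible)],
    )


class TestOperatorTable:
    def test_reversible_reaction_gives_two_operators(self):
        table = build_operator_table(reaction_model(True), cofactor_ids=())
        assert table.n_entries == 2
        assert {p.direction for op in table.operators
                for p in op.provenance} == {"forward", "reverse"}

    def test_irreversible_reaction_gives_one(self):
        table = build_operator_table(reaction_model(False))
        assert table.n_entries == 1

    def test_multi_centre_pair_skipped_with_reason(self):
        table = build_operator_table(
            reaction_model(False, pair=("OCCCCCO", "O=CCCCC=O")))
        assert len(table) == 0
        assert any("multi-centre" in reason for _, reason in table.skipped)

    def test_reaction_without_kegg_id_skipped(self):
        model = reaction_model(False)
        model.reactions[0].kegg_ids = ()
        table = build_operator_table(model)
        assert len(table) == 0

    def test_cofactor_only_sides_skipped(self):
        model = reaction_model(False)
        table = build_operator_table(model, cofactor_ids=("sub",))
        assert len(table) == 0
        assert any("no non-cofactor" in r for _, r in table.skipped)


class TestRoundTrip:
    def test_operators_regenerate_their_products(self, toy):
        table = build_operator_table(toy.model, cofactor_ids=toy.cofactor_ids)
        assert table.n_entries >= 10
        for op in table.operators:
            for prov, origin in op.sources:
                g = toy.model.metabolites[origin.substrate_id].structure
                keys = {
                    canonical_key(apply_operator(op, g, s))
                    for s in find_sites(op, g)
                }
                assert origin.product_key in keys, (prov.reaction_id,
                                                    prov.direction)

    def test_reverse_operator_regenerates_substrate(self):
        model = reaction_model(True)
        table = build_operator_table(model)
        rev = next(op for op in table.operators
                   if op.provenance[0].direction == "reverse")
        g = model.metabolites["prod"].structure
        keys = {canonical_key(apply_operator(rev, g, s))
                for s in find_sites(rev, g)}
        assert canonical_key(model.metabolites["sub"].structure) in keys

    def test_operator_count_invariant_under_atom_reordering(self):
        model = reaction_model(True)
        n_ref = build_operator_table(model).n_entries
        rng = random.Random(3)
        for _ in range(5):
            permuted = reaction_model(True)
            for met in permuted.metabolites.values():
                mol = met.structure.to_rdkit()
                order = list(range(mol.GetNumAtoms()))
                rng.shuffle(order)
                met.structure = from_rdkit(Chem.RenumberAtoms(mol, order))
            assert build_operator_table(permuted).n_entries == n_ref
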