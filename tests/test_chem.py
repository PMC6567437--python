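"""Structure parsing, atom typing, canonical keys and formulas."""

import random
import re

import pytest
from rdkit import Chem

from metexpand.atom_types import atom_type_table, element_class
from metexpand.chem import (ElementFormula, ParseError, ValenceError,
                            canonical_key, formula_of, from_rdkit,
                            parse_structure)

PANEL = [
    "CC(=O)O",                      # acetic acid
    "OCC(O)CO",                     # glycerol
    "CC(=O)C(=O)O",                 # pyruvic acid
    "NC(CCC(=O)O)C(=O)O",           # glutamic acid
    "OP(=O)(O)OCC(O)C(O)CO",        # a sugar phosphate
    "c1ccccc1O",                    # phenol
    "CSCCC(N)C(=O)O",               # methionine
    "NC(=O)c1ccccc1",               # benzamide
    "OC(=O)C(O)C(O)C(=O)O",         # tartaric acid
    "C1CC1C1CC1",                   # bicyclopropyl
    "OCC1OC(O)C(O)C(O)C1O",         # a hexose
    "CC(C)CC(N)C(=O)O",             # leucine
    "N#CCC(N)C(=O)O",               # cyanoalanine
    "CC(O)C",                       # isopropanol
    "CC(=O)C",                      # acetone
    "O=C=O",
    "OP(=O)(O)O",
    "NC(N)=O",                      # urea
    "CS(=O)C",                      # DMSO-like
    "FC(F)(F)C(=O)O",               # trifluoroacetic acid
]


def count_heavy_from_smiles(smiles: str) -> dict:
    """Independent heavy-atom counter working on SMILES tokens alone."""
    counts: dict[str, int] = {}
    i = 0
    while i < len(smiles):
        ch = smiles[i]
        if ch == "[":
            j = smiles.index("]", i)
            inner = smiles[i + 1:j]
            m = re.match(r"\d*([A-Za-z][a-z]?)", inner)
            el = m.group(1)
            if el.lower() != "h":
                el = el.capitalize()
                counts[el] = counts.get(el, 0) + 1
            i = j + 1
            continue
        two = smiles[i:i + 2]
        if two in ("Cl", "Br"):
            counts[two] = counts.get(two, 0) + 1
            i += 2
            continue
        if ch.upper() in "BCNOSPFI" and ch not in "()=#+-1234567890/\\.@":
            el = ch.upper() if ch.islower() else ch
            counts[el] = counts.get(el, 0) + 1
        i += 1
    return counts


class TestParsing:
    def test_acetate_smiles(self):
        g = parse_structure("CC(=O)O")
        assert g.n_atoms == 4
        assert sum(1 for b in g.bonds if b.order == "2") == 1

    def test_molfile_equivalent_to_smiles(self):
        g = parse_structure("CC(=O)O")
        block = Chem.MolToMolBlock(g.to_rdkit())
        g2 = parse_structure(block, "molfile")
        assert canonical_key(g2) == canonical_key(g)

    def test_two_rings_six_carbons(self):
        g = parse_structure("C1CC1C1CC1")
        assert g.n_atoms == 6
        assert all(a.element == "C" for a in g.atoms)
        assert len(g.bonds) == 7  # 6 ring bonds + 1 bridge: two rings

    def test_unparsable_raises(self):
        with pytest.raises(ParseError):
            parse_structure("not-a-smiles((")

    def test_valence_violation_names_atom(self):
        with pytest.raises(ValenceError, match="atom"):
            parse_structure("C(C)(C)(C)(C)C")

    def test_kekule_input_normalised(self):
        a = parse_structure("C1=CC=CC=C1O")
        b = parse_structure("c1ccccc1O")
        assert canonical_key(a) == canonical_key(b)


class TestAtomTypes:
    def test_carbonyl_vs_carbinol_distinct(self):
        acetone = parse_structure("CC(=O)C")
        isoprop = parse_structure("CC(O)C")
        assert acetone.atoms[1].atom_type != isoprop.atoms[1].atom_type

    def test_symmetric_methyls_identical(self):
        acetone = parse_structure("CC(=O)C")
        assert acetone.atoms[0].atom_type == acetone.atoms[3].atom_type

    def test_phosphate_vs_phosphine_distinct(self):
        ester = parse_structure("COP(=O)(O)O")
        phosphine = parse_structure("CP(C)C")
        p1 = next(a for a in ester.atoms if a.element == "P")
        p2 = next(a for a in phosphine.atoms if a.element == "P")
        assert p1.atom_type != p2.atom_type

    def test_every_emitted_code_is_documented(self):
        table = atom_type_table()
        for smi in PANEL:
            for atom in parse_structure(smi).atoms:
                code = atom.atom_type.rstrip("+-")
                assert code in table, f"{code} missing from vocabulary"
                assert element_class(atom.atom_type) == atom.element

    def test_typing_is_local(self):
        """A substituent beyond radius 1 never changes an atom's type."""
        short = parse_structure("CCCCO")
        longer = parse_structure("NCCCCO")  # amine added at the far end
        # atoms 0..1 of `short` are atoms 1..2 of `longer`, all at
        # distance >1 from the new substituent... only atom 0/1 qualify
        assert short.atoms[1].atom_type == longer.atoms[2].atom_type


class TestCanonicalKey:
    def test_stereo_ignored(self):
        d = parse_structure("C[C@H](N)C(=O)O")
        l = parse_structure("C[C@@H](N)C(=O)O")
        assert canonical_key(d) == canonical_key(l)

    @pytest.mark.parametrize("smiles", PANEL[:6])
    def test_invariant_under_atom_reordering(self, smiles):
        g = parse_structure(smiles)
        ref = canonical_key(g)
        mol = g.to_rdkit()
        rng = random.Random(20240915)
        for _ in range(100):
            order = list(range(mol.GetNumAtoms()))
            rng.shuffle(order)
            perm = from_rdkit(Chem.RenumberAtoms(mol, order))
            assert canonical_key(perm) == ref


class TestFormula:
    def test_bicarbonate(self):
        f = formula_of(parse_structure("OC([O-])=O"))
        assert f.heavy() == {"C": 1, "O": 3}
        assert f.counts["H"] == 1
        assert f.charge == -1

    def test_water(self):
        f = formula_of(parse_structure("O"))
        assert f.counts == {"O": 1, "H": 2}

    def test_atp_heavy_atoms(self):
        atp = parse_structure(
            "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O")
        assert formula_of(atp).heavy() == {"C": 10, "N": 5, "O": 13, "P": 3}

    @pytest.mark.parametrize("smiles", PANEL)
    def test_heavy_counts_match_token_oracle(self, smiles):
        assert formula_of(parse_structure(smiles)).heavy() == \
            count_heavy_from_smiles(smiles)

    def test_formula_string_round_trip(self):
        f = ElementFormula.from_string("C10H14N5O8P", charge=0)
        assert f.to_string() == "C10H14N5O8P"
        assert ElementFormula.from_string(f.to_string()).counts == f.counts
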