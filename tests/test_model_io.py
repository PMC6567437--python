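"""Model loading, serialisation round-trips and substrate pools."""

import json

import pytest

from metexpand.fixtures import write_universe
from metexpand.model_io import (ConcentrationTable, MetabolicModel, Metabolite,
                                ModelError, load_model, save_model,
                                select_substrate_pool, substrate_pools)

TINY_MODEL = {
    "id": "tiny",
    "metabolites": [
        {"id": f"{m}_c", "name": m, "compartment": "c", "formula": "C3H6O3"}
        for m in ["a", "b", "c", "d", "e", "f"]
    ],
    "reactions": [
        {"id": f"R{i}", "name": f"R{i}",
         "metabolites": {f"{s}_c": -1, f"{p}_c": 1},
         "lower_bound": -1000, "upper_bound": 1000,
         "gene_reaction_rule": "g1"}
        for i, (s, p) in enumerate([("a", "b"), ("b", "c"), ("c", "d"),
                                    ("e", "f")])
    ],
    "genes": [{"id": "g1", "name": "g1"}],
    "compartments": {"c": "cytosol"},
    "version": "1",
}


def write_json(tmp_path, data, name="model.json"):
    path = tmp_path / name
    path.write_text(json.dumps(data))
    return path


class TestLoad:
    def test_tiny_bigg_json_counts(self, tmp_path):
        model = load_model(write_json(tmp_path, TINY_MODEL))
        assert len(model.metabolites) == 6
        assert len(model.reactions) == 4
        assert all(r.reversible for r in model.reactions)

    def test_empty_reaction_list_is_valid(self, tmp_path):
        data = dict(TINY_MODEL, reactions=[])
        model = load_model(write_json(tmp_path, data))
        assert model.reactions == []

    def test_unknown_metabolite_error_names_it(self, tmp_path):
        data = json.loads(json.dumps(TINY_MODEL))
        data["reactions"][0]["metabolites"]["X_c"] = 1
        with pytest.raises(ModelError, match="X_c"):
            load_model(write_json(tmp_path, data))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope.json")

    def test_structureless_metabolites_flagged(self, tmp_path):
        path = write_json(tmp_path, TINY_MODEL)
        sidecar = tmp_path / "structures.tsv"
        sidecar.write_text("a\tCCO\nb\tCC=O\n")
        model = load_model(path, structures=sidecar)
        assert model.metabolites["a"].has_structure
        assert not model.metabolites["c"].has_structure
        assert model.structure_bearing() == {"a", "b"}


class TestRoundTrip:
    def test_toy_bundle_load_save_load(self, toy, tmp_path):
        paths = write_universe(toy, tmp_path / "bundle")
        m1 = load_model(paths["model"], structures=paths["structures"])
        save_model(m1, tmp_path / "again.json")
        m2 = load_model(tmp_path / "again.json",
                        structures=paths["structures"])
        assert sorted(m1.metabolites) == sorted(m2.metabolites)
        assert [(r.id, sorted(r.stoichiometry.items()), r.ec_numbers,
                 r.kegg_ids, r.reversible) for r in m1.reactions] == \
               [(r.id, sorted(r.stoichiometry.items()), r.ec_numbers,
                 r.kegg_ids, r.reversible) for r in m2.reactions]

    def test_loaded_equals_generated(self, toy, tmp_path):
        paths = write_universe(toy, tmp_path / "bundle")
        loaded = load_model(paths["model"], structures=paths["structures"])
        assert sorted(loaded.metabolites) == sorted(toy.model.metabolites)
        assert len(loaded.reactions) == len(toy.model.reactions)

    def test_sbml_equivalent_to_json(self, toy, tmp_path):
        import cobra.io

        paths = write_universe(toy, tmp_path / "bundle")
        cmodel = cobra.io.load_json_model(str(paths["model"]))
        sbml_path = tmp_path / "model.xml"
        cobra.io.write_sbml_model(cmodel, str(sbml_path))
        from_json = load_model(paths["model"])
        from_sbml = load_model(sbml_path, format="sbml")
        assert sorted(from_sbml.metabolites) == sorted(from_json.metabolites)
        assert {(r.id, r.kegg_ids, r.reversible) for r in from_sbml.reactions} \
            == {(r.id, r.kegg_ids, r.reversible) for r in from_json.reactions}


def small_model():
    mets = {}
    for mid, smi in [("A", "CCO"), ("B", "CC=O"), ("C", "CCC")]:
        from metexpand import chem
        g = chem.parse_structure(smi)
        mets[mid] = Metabolite(id=mid, name=mid, structure=g)
    mets["D"] = Metabolite(id="D", name="no structure")
    return MetabolicModel(id="m", metabolites=mets, reactions=[])


class TestSubstratePool:
    def test_strict_threshold(self):
        model = small_model()
        conc = ConcentrationTable({"A": 5.0, "B": 0.5, "C": 1.0})
        assert select_substrate_pool(model, conc, 1.0) == {"A"}

    def test_empty_table(self):
        assert select_substrate_pool(small_model(),
                                     ConcentrationTable({}), 1.0) == set()

    def test_zero_threshold_takes_all_positive(self):
        model = small_model()
        conc = ConcentrationTable({"A": 5.0, "B": 0.5, "C": 1.0})
        assert select_substrate_pool(model, conc, 0.0) == {"A", "B", "C"}

    def test_pools_partition_structure_bearing(self):
        model = small_model()
        conc = ConcentrationTable({"A": 5.0, "B": 0.5})
        pools = substrate_pools(model, conc, 1.0)
        assert pools.high | pools.remainder == model.structure_bearing()
        assert not pools.high & pools.remainder
        # the structure-less metabolite never enters either pool
        assert "D" not in pools.high | pools.remainder

    def test_negative_concentration_rejected(self):
        with pytest.raises(ModelError):
            ConcentrationTable({"A": -1.0})

    def test_duplicate_row_rejected(self, tmp_path):
        path = tmp_path / "conc.tsv"
        path.write_text("metabolite_id\tconcentration_uM\nA\t1\nA\t2\n")
        with pytest.raises(ModelError, match="duplicate"):
            ConcentrationTable.from_tsv(path)

    def test_tsv_round_trip(self, tmp_path):
        conc = ConcentrationTable({"A": 5.0, "B": 0.25})
        conc.to_tsv(tmp_path / "c.tsv")
        again = ConcentrationTable.from_tsv(tmp_path / "c.tsv")
        assert again.values == conc.values
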