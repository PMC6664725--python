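"""Cleansing rules, IC50 normalization, and interaction-table assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twincnn.gdsc_io import (CellLineRecord, DataError, DrugRecord,
                             InteractionTable, SchemaError,
                             build_interaction_table, denormalize_ic50,
                             load_cell_lines, load_drug_list, load_table,
                             max_conc_subset, normalize_ic50, save_table)


def _write(path, text):
    path.write_text(text)
    return path


class TestLoadDrugList:
    def test_duplicates_removed_keeping_first(self, tmp_path):
        drugs = _write(tmp_path / "d.csv",
                       "drug_id,name\nA,aa\nB,bb\nA,dup\nC,cc\nB,dup\n")
        smap = _write(tmp_path / "s.csv",
                      "drug_id,canonical_smiles\nA,CC\nB,CO\nC,CN\n")
        records = load_drug_list(drugs, smap)
        assert [r.drug_id for r in records] == ["A", "B", "C"]
        assert records[0].name == "aa"

    def test_missing_smiles_dropped_with_warning(self, tmp_path, caplog):
        drugs = _write(tmp_path / "d.csv",
                       "drug_id,name\nA,aa\nB,bb\nC,cc\nD,dd\n")
        smap = _write(tmp_path / "s.csv",
                      "drug_id,canonical_smiles\nA,CC\nB,CO\nD,CN\n")
        with caplog.at_level("WARNING"):
            records = load_drug_list(drugs, smap)
        assert [r.drug_id for r in records] == ["A", "B", "D"]
        assert "C" in caplog.text

    def test_row_order_does_not_matter(self, tmp_path):
        smap = _write(tmp_path / "s.csv",
                      "drug_id,canonical_smiles\nA,CC\nB,CO\nC,CN\n")
        d1 = _write(tmp_path / "d1.csv", "drug_id,name\nC,cc\nA,aa\nB,bb\n")
        d2 = _write(tmp_path / "d2.csv", "drug_id,name\nA,aa\nB,bb\nC,cc\n")
        assert load_drug_list(d1, smap) == load_drug_list(d2, smap)

    def test_schema_errors(self, tmp_path):
        bad = _write(tmp_path / "d.csv", "id,name\nA,aa\n")
        smap = _write(tmp_path / "s.csv", "drug_id,canonical_smiles\nA,CC\n")
        with pytest.raises(SchemaError):
            load_drug_list(bad, smap)


class TestLoadCellLines:
    @staticmethod
    def _cells_csv(tmp_path, rows):
        header = "cell_id,tissue,f1,f2,f3"
        return _write(tmp_path / "c.csv", "\n".join([header] + rows) + "\n")

    def test_incomplete_cells_removed(self, tmp_path):
        path = self._cells_csv(tmp_path, ["c1,lung,0,1,0",
                                          "c2,lung,1,,0",
                                          "c3,blood,1,1,1"])
        cells = load_cell_lines(path, required_features=3)
        assert [c.cell_id for c in cells] == ["c1", "c3"]

    def test_boundary_exactly_at_threshold_is_kept(self, tmp_path):
        path = self._cells_csv(tmp_path, ["c1,lung,0,1,", "c2,lung,1,0,1"])
        cells = load_cell_lines(path, required_features=2)
        assert [c.cell_id for c in cells] == ["c1", "c2"]

    def test_all_complete_is_a_no_op(self, tmp_path):
        path = self._cells_csv(tmp_path, ["c1,lung,0,1,0", "c2,blood,1,0,1"])
        assert len(load_cell_lines(path)) == 2

    def test_long_format_is_equivalent(self, tmp_path):
        wide = self._cells_csv(tmp_path, ["c1,lung,0,1,1"])
        long = _write(tmp_path / "long.csv",
                      "cell_id,tissue,feature_name,value\n"
                      "c1,lung,f1,0\nc1,lung,f2,1\nc1,lung,f3,1\n")
        w, l = load_cell_lines(wide)[0], load_cell_lines(long)[0]
        np.testing.assert_array_equal(w.features, l.features)

    def test_unknown_feature_name_rejected(self, tmp_path):
        path = self._cells_csv(tmp_path, ["c1,lung,0,1,0"])
        with pytest.raises(SchemaError):
            load_cell_lines(path, feature_catalogue=["f1", "f2"])


class TestNormalization:
    def test_midpoint(self):
        assert normalize_ic50(0.0) == pytest.approx(0.5)

    def test_derived_value(self):
        # x = ln(1e-3): 1 / (1 + (1e-3)^(-0.1)) = 1 / (1 + 10^0.3)
        assert normalize_ic50(np.log(1e-3)) == pytest.approx(
            1.0 / (1.0 + 10 ** 0.3), abs=1e-10)
        assert normalize_ic50(np.log(1e-3)) == pytest.approx(0.3339, abs=5e-5)

    def test_monotone_increasing(self):
        x = np.linspace(-40, 40, 2001)
        assert (np.diff(normalize_ic50(x)) > 0).all()

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            normalize_ic50(np.inf)

    def test_denormalize_examples(self):
        assert denormalize_ic50(0.5) == pytest.approx(0.0, abs=1e-12)
        assert denormalize_ic50(1.0 / (1.0 + 10 ** 0.3)) == pytest.approx(
            np.log(1e-3), abs=1e-9)
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                denormalize_ic50(bad)

    @given(st.floats(-30, 30))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_bijection(self, x):
        assert denormalize_ic50(normalize_ic50(x)) == pytest.approx(
            x, abs=1e-9)


@pytest.fixture()
def toy_entities():
    drugs = [DrugRecord("d1", "n1", "CC"), DrugRecord("d2", "n2", "CO"),
             DrugRecord("d3", "n3", "CN")]
    cells = [CellLineRecord("c1", "lung", np.array([0, 1], dtype=np.uint8)),
             CellLineRecord("c2", "blood", np.array([1, 1], dtype=np.uint8))]
    return drugs, cells


class TestInteractionTable:
    IC50 = ("drug_id,cell_id,log_ic50,below_max_conc\n"
            "d1,c1,-2.0,1\nd1,c2,0.5,0\nd2,c1,-1.0,1\n"
            "d3,c1,3.0,0\nd3,c2,-4.0,1\n")

    def test_mask_bookkeeping(self, tmp_path, toy_entities):
        drugs, cells = toy_entities
        table = build_interaction_table(
            drugs, cells, _write(tmp_path / "i.csv", self.IC50))
        assert table.known_mask.sum() == 5
        assert table.known_mask[1, 1] == 0  # (d2, c2) unmeasured
        assert table.below_max_conc_mask.sum() == 3
        v = table.values[table.known_mask.astype(bool)]
        assert (v > 0).all() and (v < 1).all()
        assert table.values[0, 0] == pytest.approx(normalize_ic50(-2.0))

    def test_rows_for_dropped_entities_excluded(self, tmp_path, toy_entities):
        drugs, cells = toy_entities
        extra = self.IC50 + "dX,c1,1.0,1\nd1,cX,1.0,1\n"
        table = build_interaction_table(
            drugs, cells, _write(tmp_path / "i.csv", extra))
        assert table.known_mask.sum() == 5

    def test_duplicate_pair_rejected(self, tmp_path, toy_entities):
        drugs, cells = toy_entities
        dup = self.IC50 + "d1,c1,0.0,1\n"
        with pytest.raises(DataError, match="d1, c1"):
            build_interaction_table(drugs, cells,
                                    _write(tmp_path / "i.csv", dup))

    def test_below_max_conc_defaults_to_one(self, tmp_path, toy_entities):
        drugs, cells = toy_entities
        table = build_interaction_table(
            drugs, cells,
            _write(tmp_path / "i.csv",
                   "drug_id,cell_id,log_ic50\nd1,c1,-2.0\nd2,c2,1.0\n"))
        assert table.below_max_conc_fraction() == 1.0

    def test_max_conc_subset_masks(self, tmp_path, toy_entities):
        drugs, cells = toy_entities
        table = build_interaction_table(
            drugs, cells, _write(tmp_path / "i.csv", self.IC50))
        sub = max_conc_subset(table)
        assert sub.known_mask.sum() == 3
        np.testing.assert_array_equal(
            sub.known_mask, table.known_mask & table.below_max_conc_mask)
        np.testing.assert_array_equal(sub.values, table.values)

    def test_serialization_round_trip(self, tmp_path, toy_entities):
        drugs, cells = toy_entities
        table = build_interaction_table(
            drugs, cells, _write(tmp_path / "i.csv", self.IC50))
        save_table(table, tmp_path / "tbl")
        back = load_table(tmp_path / "tbl")
        assert back.known_mask.sum() == table.known_mask.sum()
        np.testing.assert_array_equal(back.values, table.values)
        assert back.drugs == table.drugs
        assert [c.cell_id for c in back.cells] == [c.cell_id for c in table.cells]

    def test_pipeline_is_deterministic(self, tmp_path, toy_entities):
        drugs, cells = toy_entities
        path = _write(tmp_path / "i.csv", self.IC50)
        t1 = build_interaction_table(drugs, cells, path)
        t2 = build_interaction_table(drugs, cells, path)
        np.testing.assert_array_equal(t1.values, t2.values)
        np.testing.assert_array_equal(t1.known_mask, t2.known_mask)
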