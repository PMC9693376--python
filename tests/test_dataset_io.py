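"""Index parsing, affinity-case assembly, splitting, table round-trips."""

import json

import numpy as np
import pytest

from hnnaffinity.dataset_io import (
    ComplexRecord,
    assemble_case,
    merge_sources,
    parse_index_file,
    read_dataset_table,
    split_dataset,
    write_dataset_table,
)
from hnnaffinity.featurize import AffinityLabel

INDEX_TEXT = """\
# ==============================================================
# List of protein-ligand complexes with binding data
# ==============================================================
1abc  2.00  2010   6.00  Kd=1uM       // 1abc.pdf (lig)
2def  1.80  2015   3.00  Ki>10mM      // 2def.pdf (xyz)
3ghi  2.40  2001   7.30  Kd=50nM      // 3ghi.pdf (abc)
4jkl  1.50  2019   5.22  IC50=6uM     // 4jkl.pdf (qrs)
5mno  2.10  2007   8.00  Kd~10nM      // 5mno.pdf (tuv)
badln 9.99  1999   1.00  Kx=??        // unparseable affinity
"""


class TestParseIndexFile:
    def test_fields_of_exact_kd_line(self):
        recs = {r.id: r for r in parse_index_file(INDEX_TEXT)}
        r = recs["1abc"]
        assert r.label.kind == "Kd"
        assert r.label.qualifier == "exact"
        assert r.label.pk == pytest.approx(6.0)

    def test_qualifiers_and_kinds(self):
        recs = {r.id: r for r in parse_index_file(INDEX_TEXT)}
        assert recs["2def"].label.kind == "Ki"
        assert recs["2def"].label.qualifier == "lower_bound"
        assert recs["4jkl"].label.kind == "IC50"
        assert recs["5mno"].label.qualifier == "approximate"

    def test_comments_and_malformed_skipped(self):
        recs = parse_index_file(INDEX_TEXT)
        assert len(recs) == 5
        assert "badln" not in {r.id for r in recs}

    def test_recomputed_pk_agrees_with_neglog_column(self):
        for r in parse_index_file(INDEX_TEXT):
            stated = {"1abc": 6.0, "2def": 2.0, "3ghi": 7.30, "4jkl": 5.22,
                      "5mno": 8.0}[r.id]
            assert r.label.pk == pytest.approx(stated, abs=0.05)

    def test_all_comments_is_error(self):
        with pytest.raises(ValueError, match="no parseable"):
            parse_index_file("# nothing here\n# at all\n")


def _labelled(n_kd=3, n_ki=2, censored=0):
    recs = []
    for i in range(n_kd):
        recs.append(ComplexRecord(id=f"kd{i}",
                                  label=AffinityLabel.from_pk("Kd", 5.0 + i)))
    for i in range(n_ki):
        recs.append(ComplexRecord(id=f"ki{i}",
                                  label=AffinityLabel.from_pk("Ki", 4.0 + i)))
    for i in range(censored):
        recs.append(ComplexRecord(
            id=f"cen{i}",
            label=AffinityLabel.from_pk("Kd", 3.0, qualifier="lower_bound")))
    return recs


class TestAssembleCase:
    def test_counts_per_case(self):
        recs = _labelled()
        assert len(assemble_case(recs, "kd_only")) == 3
        assert len(assemble_case(recs, "ki_only")) == 2
        assert len(assemble_case(recs, "kd_and_ki")) == 5

    def test_censored_excluded_by_default(self):
        recs = _labelled(censored=1)
        ids = {r.id for r in assemble_case(recs, "kd_only")}
        assert "cen0" not in ids
        ids = {r.id for r in assemble_case(recs, "kd_only", include_censored=True)}
        assert "cen0" in ids

    def test_union_property(self):
        recs = _labelled(n_kd=4, n_ki=3)
        both = {r.id for r in assemble_case(recs, "kd_and_ki")}
        kd = {r.id for r in assemble_case(recs, "kd_only")}
        ki = {r.id for r in assemble_case(recs, "ki_only")}
        assert kd | ki == both
        assert not kd & ki

    def test_empty_result_errors(self):
        with pytest.raises(ValueError, match="ki_only"):
            assemble_case(_labelled(n_ki=0), "ki_only")

    def test_unknown_case_errors(self):
        with pytest.raises(ValueError):
            assemble_case(_labelled(), "everything")


class TestMergeSources:
    def test_refined_wins_on_duplicates(self):
        refined = [ComplexRecord(id="x", smiles="C",
                                 label=AffinityLabel.from_pk("Kd", 5.0))]
        general = [ComplexRecord(id="x", smiles="N",
                                 label=AffinityLabel.from_pk("Kd", 4.0)),
                   ComplexRecord(id="y", label=AffinityLabel.from_pk("Ki", 3.0))]
        merged = {r.id: r for r in merge_sources(refined, general)}
        assert merged["x"].smiles == "C"
        assert merged["x"].source == "refined"
        assert merged["y"].source == "general"


class TestSplitDataset:
    def test_partition(self):
        recs = _labelled(6, 4)
        split = split_dataset(recs, test_count=2, seed=7)
        assert len(split.train) == 8 and len(split.test) == 2
        train_ids = {r.id for r in split.train}
        test_ids = {r.id for r in split.test}
        assert not train_ids & test_ids
        assert train_ids | test_ids == {r.id for r in recs}

    def test_deterministic_given_seed(self):
        recs = _labelled(6, 4)
        a = split_dataset(recs, test_count=3, seed=7)
        b = split_dataset(recs, test_count=3, seed=7)
        assert a.manifest == b.manifest

    def test_explicit_id_list(self):
        recs = _labelled(3, 2)
        split = split_dataset(recs, test_ids=["kd0", "ki1"])
        assert {r.id for r in split.test} == {"kd0", "ki1"}

    def test_oversized_test_errors(self):
        with pytest.raises(ValueError):
            split_dataset(_labelled(2, 1), test_count=3)

    def test_manifest_round_trip(self, tmp_path):
        split = split_dataset(_labelled(5, 3), test_fraction=0.25, seed=1)
        split.write_manifest(tmp_path / "m.json")
        loaded = json.loads((tmp_path / "m.json").read_text())
        assert loaded == split.manifest


class TestDatasetTable:
    def test_round_trip(self, small_records, tmp_path):
        path = tmp_path / "data.csv"
        write_dataset_table(small_records, path)
        back = read_dataset_table(path)
        assert [r.id for r in back] == [r.id for r in small_records]
        for a, b in zip(small_records, back):
            assert a.smiles == b.smiles
            assert a.pocket_seq == b.pocket_seq
            assert b.label.pk == pytest.approx(a.label.pk, abs=1e-9)
            np.testing.assert_allclose(b.descriptors, a.descriptors, atol=1e-9)

    def test_tsv_round_trip(self, small_records, tmp_path):
        path = tmp_path / "data.tsv"
        write_dataset_table(small_records, path)
        assert [r.id for r in read_dataset_table(path)] == ["c1", "c2", "c3"]

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,pocket_seq,pk\na,GG,5.0\n")
        with pytest.raises(ValueError, match="smiles"):
            read_dataset_table(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("id,smiles,pocket_seq,pk\na,C,G,5.0\na,N,A,6.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_dataset_table(path)

    def test_value_unit_kind_columns(self, tmp_path):
        path = tmp_path / "vu.csv"
        path.write_text("id,smiles,pocket_seq,value,unit,kind\na,C,G,1,uM,Kd\n")
        (rec,) = read_dataset_table(path)
        assert rec.label.pk == pytest.approx(6.0)
        assert rec.label.kind == "Kd"
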