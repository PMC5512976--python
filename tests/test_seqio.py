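import pytest

from protquant import seqio
from protquant.seqio import (DuplicateIdentifierError, FastaFormatError,
                             SequenceRecord, SequenceSet)


def make_set(*specs, unique_ids=False, name="t"):
    return SequenceSet(name, unique_ids,
                       [SequenceRecord(i, f, list(d)) for i, f, d in specs])


class TestReadFasta:
    def test_parses_records_headers_and_multiline_bodies(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">s1 some description\nACD\n>s2\nGH\nK\n")
        sset = seqio.read_fasta(path)
        assert len(sset) == 2
        assert sset[0].identifier == "s1"
        assert sset[0].description == "s1 some description"
        assert sset[0].data == ["A", "C", "D"]
        assert sset[1].data == ["G", "H", "K"]
        assert all(r.feature_name == "fasta" for r in sset)

    def test_empty_file_gives_empty_set(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert len(seqio.read_fasta(path)) == 0

    def test_case_folded_to_upper_by_default_but_preservable(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">s1\nacDg\n")
        assert seqio.read_fasta(path)[0].data == list("ACDG")
        assert seqio.read_fasta(path, uppercase=False)[0].data == list("acDg")

    def test_content_before_first_header_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("ACDEF\n>s1\nACD\n")
        with pytest.raises(FastaFormatError):
            seqio.read_fasta(path)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(OSError):
            seqio.read_fasta(tmp_path / "nope.fasta")

    def test_empty_body_yields_empty_record_with_warning(self, tmp_path):
        path = tmp_path / "in.fasta"
        path.write_text(">s1\n>s2\nACD\n")
        with pytest.warns(UserWarning, match="empty body"):
            sset = seqio.read_fasta(path)
        assert sset[0].data == []
        assert sset[1].data == ["A", "C", "D"]


class TestWriteFasta:
    def test_single_record_exact_text(self, tmp_path):
        path = tmp_path / "out.fasta"
        seqio.write_fasta(make_set(("s1", "fasta", "AC")), path)
        assert path.read_text() == ">s1\nAC\n"

    def test_wraps_at_line_width(self, tmp_path):
        path = tmp_path / "out.fasta"
        seqio.write_fasta(make_set(("s1", "fasta", "A" * 70)), path,
                          line_width=60)
        lines = path.read_text().splitlines()
        assert [len(l) for l in lines[1:]] == [60, 10]

    def test_numeric_record_raises_naming_the_record(self, tmp_path):
        sset = SequenceSet("t", records=[
            SequenceRecord("n1", "charge", [0.5, 1.0])])
        with pytest.raises(TypeError, match="n1"):
            seqio.write_fasta(sset, tmp_path / "out.fasta")

    def test_round_trip_on_random_fixture(self, tmp_path, random_fixture_set):
        path = tmp_path / "rt.fasta"
        seqio.write_fasta(random_fixture_set, path)
        back = seqio.read_fasta(path)
        assert back.ids() == random_fixture_set.ids()
        assert [r.data for r in back] == [r.data for r in random_fixture_set]


class TestMerge:
    def test_concatenates_preserving_order(self):
        a = make_set(("a1", "fasta", "AC"), ("a2", "fasta", "GG"))
        b = make_set(("b1", "fasta", "K"), ("b2", "fasta", "W"),
                     ("b3", "fasta", "Y"))
        merged = seqio.merge(a, b, "m")
        assert len(merged) == 5
        assert merged.ids() == ["a1", "a2", "b1", "b2", "b3"]

    def test_merge_with_empty_set_is_identity_on_records(self):
        a = make_set(("a1", "fasta", "AC"))
        merged = seqio.merge(a, SequenceSet("empty"), "m")
        assert merged.ids() == a.ids()
        assert [r.data for r in merged] == [r.data for r in a]

    def test_collision_under_unique_ids_raises(self):
        a = make_set(("s1", "fasta", "AC"), unique_ids=True)
        b = make_set(("s1", "fasta", "GG"), unique_ids=True)
        with pytest.raises(DuplicateIdentifierError):
            seqio.merge(a, b, "m")

    def test_record_order_associative(self):
        a = make_set(("a", "fasta", "A"))
        b = make_set(("b", "fasta", "C"))
        c = make_set(("c", "fasta", "G"))
        left = seqio.merge(seqio.merge(a, b, "x"), c, "y")
        right = seqio.merge(a, seqio.merge(b, c, "x"), "y")
        assert left.ids() == right.ids() == ["a", "b", "c"]


class TestColumns:
    SET = make_set(("s1", "fasta", "ACD"), ("s2", "fasta", "GHK"))

    def test_extracts_requested_indices_per_record(self):
        assert seqio.columns(self.SET, [0, 2]) == [["A", "D"], ["G", "K"]]

    def test_transpose_swaps_rows_and_columns(self):
        assert seqio.columns(self.SET, [0, 2], transpose=True) == \
            [["A", "G"], ["D", "K"]]

    def test_empty_indices_give_empty_rows(self):
        assert seqio.columns(self.SET, []) == [[], []]

    def test_out_of_range_names_the_record(self):
        bad = make_set(("s1", "fasta", "ACD"), ("short", "fasta", "GH"))
        with pytest.raises(IndexError, match="short"):
            seqio.columns(bad, [2])


class TestSubset:
    def test_filters_by_predicate_preserving_order(self):
        sset = make_set(("a", "fasta", "AC"), ("b", "fasta", "ACD"),
                        ("c", "fasta", "ACDE"))
        out = seqio.subset(sset, lambda r: len(r) >= 3)
        assert out.ids() == ["b", "c"]
        assert len(sset) == 3  # original untouched

    def test_always_false_and_always_true(self):
        sset = make_set(("a", "fasta", "AC"), ("b", "fasta", "GG"))
        assert len(seqio.subset(sset, lambda r: False)) == 0
        out = seqio.subset(sset, lambda r: True)
        assert out.ids() == sset.ids()

    def test_raising_predicate_propagates_with_identifier(self):
        sset = make_set(("culprit", "fasta", "AC"))

        def boom(rec):
            raise RuntimeError("bad")

        with pytest.raises(RuntimeError, match="culprit"):
            seqio.subset(sset, boom)


class TestCompact:
    def test_joins_single_values_per_identifier(self):
        sset = SequenceSet("t", records=[
            SequenceRecord("s1", "net_charge", [0.1]),
            SequenceRecord("s1", "mean_hydropathy", [2.0])])
        out = seqio.compact(sset)
        assert len(out) == 1
        assert out[0].data == [0.1, 2.0]
        assert out[0].feature_name == "net_charge:mean_hydropathy"

    def test_single_record_is_identity(self):
        sset = SequenceSet("t", records=[SequenceRecord("s1", "f", [3.0])])
        out = seqio.compact(sset)
        assert out[0].data == [3.0]

    def test_three_identifiers_times_two_features(self):
        # hand enumeration: values v(id, feat) laid out feature-major
        recs = []
        for feat, base in [("f1", 10), ("f2", 20)]:
            for k, ident in enumerate(["a", "b", "c"]):
                recs.append(SequenceRecord(ident, feat, [base + k]))
        out = seqio.compact(SequenceSet("t", records=recs))
        assert len(out) == 3
        assert {r.identifier: r.data for r in out} == {
            "a": [10, 20], "b": [11, 21], "c": [12, 22]}

    def test_multi_value_record_rejected(self):
        sset = SequenceSet("t", records=[SequenceRecord("s1", "f", [1, 2])])
        with pytest.raises(ValueError):
            seqio.compact(sset)

    def test_strict_mode_rejects_ragged_feature_lists(self):
        sset = SequenceSet("t", records=[
            SequenceRecord("a", "f1", [1]), SequenceRecord("a", "f2", [2]),
            SequenceRecord("b", "f1", [3])])
        assert [len(r) for r in seqio.compact(sset)] == [2, 1]
        with pytest.raises(ValueError, match="ragged"):
            seqio.compact(sset, strict=True)


def test_write_table_exports_identifier_plus_feature_columns(tmp_path):
    sset = SequenceSet("t", records=[
        SequenceRecord("s1", "net_charge", [0.1]),
        SequenceRecord("s1", "entropy", [2.0]),
        SequenceRecord("s2", "net_charge", [0.5]),
        SequenceRecord("s2", "entropy", [1.5])])
    path = tmp_path / "table.tsv"
    seqio.write_table(seqio.compact(sset), path)
    lines = path.read_text().splitlines()
    assert lines[0] == "identifier\tnet_charge\tentropy"
    assert lines[1].split("\t") == ["s1", "0.1", "2"]
    assert lines[2].split("\t")[0] == "s2"
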