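import pytest

from oracles import best_two_partition_1d
from protquant import mapping as mp
from protquant.mapping import (AAIndexFormatError, PropertyMapping, RAISE,
                               UnknownSymbolError)
from protquant.seqio import SequenceRecord


def rec(seq, ident="s1"):
    return SequenceRecord(ident, "fasta", list(seq))


class TestApplyMapping:
    def test_substitutes_default_for_unknown_symbols(self):
        m = PropertyMapping("t", {"A": 1, "C": 2}, default=0)
        out = mp.apply_mapping(m, rec("ACX"))
        assert out.data == [1, 2, 0]
        assert out.feature_name == "t"
        assert len(out) == 3

    def test_identity_mapping_reproduces_input(self):
        m = PropertyMapping("id", {s: s for s in "ACDG"})
        assert mp.apply_mapping(m, rec("GDCA")).data == list("GDCA")

    def test_error_default_names_position_and_symbol(self):
        m = PropertyMapping("t", {"A": 1.0}, default=RAISE)
        with pytest.raises(UnknownSymbolError, match="position 1"):
            mp.apply_mapping(m, rec("AXA"))

    def test_length_preserved_for_any_input(self):
        m = PropertyMapping("t", {"A": 1.0}, default=-1.0)
        for seq in ["", "A", "AAXX", "XXXXXXX"]:
            assert len(mp.apply_mapping(m, rec(seq))) == len(seq)


def aaindex_record(accession, values, description="synthetic scale"):
    rows = [values[:10], values[10:]]
    body = "\n".join("    " + "  ".join(str(v) for v in row) for row in rows)
    return (f"H {accession}\nD {description}\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T"
            "     G/W     H/Y     I/V\n" + body + "\n//\n")


class TestParseAAindex1:
    def test_two_row_ten_column_layout_decoded(self):
        # values 1..20 in file order -> A=1, R=2, ..., I=10, L=11, ..., V=20
        text = aaindex_record("SYNT000001", list(range(1, 21)))
        m = mp.parse_aaindex1(text, "SYNT000001")
        expect = dict(zip(mp.AAINDEX_ROW1 + mp.AAINDEX_ROW2,
                          [float(v) for v in range(1, 21)]))
        assert m.table == expect
        assert m.misc["accession"] == "SYNT000001"

    def test_na_value_left_missing_and_defaulted_on_application(self):
        values = list(range(1, 21))
        values[4] = "NA"  # fifth file position = residue C
        text = aaindex_record("SYNT000002", values)
        m = mp.parse_aaindex1(text, "SYNT000002", default=-9.0)
        assert "C" not in m.table
        assert mp.apply_mapping(m, rec("AC")).data == [1.0, -9.0]

    def test_second_record_of_multi_record_file_selected(self):
        text = aaindex_record("SYNT000001", list(range(1, 21))) + \
            aaindex_record("SYNT000003", [v * 10 for v in range(1, 21)])
        m = mp.parse_aaindex1(text, "SYNT000003")
        assert m.table["A"] == 10.0 and m.table["V"] == 200.0

    def test_missing_accession_raises(self):
        text = aaindex_record("SYNT000001", list(range(1, 21)))
        with pytest.raises(AAIndexFormatError, match="not found"):
            mp.parse_aaindex1(text, "NOPE")

    def test_wrong_value_count_is_format_error(self):
        text = aaindex_record("SYNT000004", list(range(1, 20)))
        with pytest.raises(AAIndexFormatError, match="20 values"):
            mp.parse_aaindex1(text, "SYNT000004")

    def test_shipped_sample_file_matches_predefined_hydropathy(self):
        from importlib import resources
        text = (resources.files("protquant") / "data" /
                "aaindex1_sample.txt").read_text()
        m = mp.parse_aaindex1(text, "KYTJ820101")
        assert m.table == mp.load_predefined("hydropathy").table


class TestPredefined:
    def test_all_predefined_cover_the_twenty_amino_acids(self):
        for name in ["hydropathy", "charge", "volume"]:
            m = mp.load_predefined(name)
            assert set(m.table) == set(mp.AMINO_ACIDS)

    def test_charge_signs(self):
        charge = mp.load_predefined("charge")
        assert charge["K"] == charge["R"] == 1
        assert charge["D"] == charge["E"] == -1
        assert charge["H"] == charge["A"] == 0

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            mp.load_predefined("nope")

    def test_mapping_file_round_trip(self, tmp_path):
        m = mp.load_predefined("hydropathy")
        path = tmp_path / "hydro.tsv"
        mp.write_mapping(m, path)
        back = mp.read_mapping(path, name="hydropathy")
        assert back.table == m.table


class TestSimplifyThresholds:
    def test_classes_count_thresholds_at_or_below_value(self):
        m = PropertyMapping("t", {"A": -1.0, "C": 0.5, "D": 2.0})
        out = mp.simplify_thresholds(m, [0, 1])
        assert out.table == {"A": 0, "C": 1, "D": 2}

    def test_no_thresholds_collapse_to_one_class(self):
        m = PropertyMapping("t", {"A": -1.0, "C": 5.0})
        assert set(mp.simplify_thresholds(m, []).table.values()) == {0}

    def test_boundary_value_goes_to_upper_class(self):
        m = PropertyMapping("t", {"A": 1.0, "C": 0.999})
        out = mp.simplify_thresholds(m, [1.0])
        assert out.table == {"A": 1, "C": 0}

    def test_unsorted_thresholds_rejected(self):
        m = PropertyMapping("t", {"A": 1.0, "C": 2.0})
        with pytest.raises(ValueError):
            mp.simplify_thresholds(m, [2, 1])

    def test_labels_substituted(self):
        m = PropertyMapping("t", {"A": -1.0, "C": 2.0})
        out = mp.simplify_thresholds(m, [0], labels=["neg", "pos"])
        assert out.table == {"A": "neg", "C": "pos"}


class TestSimplifyLinear:
    def test_k2_threshold_at_midrange_half_open(self):
        m = PropertyMapping("t", {"A": 0.0, "B": 1.0, "C": 2.0, "D": 3.0,
                                  "E": 4.0})
        out = mp.simplify_linear(m, 2)
        assert out.table == {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1}

    def test_k4_on_five_equally_spaced_values(self):
        m = PropertyMapping("t", {s: float(v) for s, v in
                                  zip("ABCDE", range(5))})
        out = mp.simplify_linear(m, 4)
        assert [out.table[s] for s in "ABCDE"] == [0, 1, 2, 3, 3]

    def test_k1_is_constant_mapping(self):
        m = PropertyMapping("t", {"A": 0.0, "C": 7.0})
        assert set(mp.simplify_linear(m, 1).table.values()) == {0}

    def test_two_distinct_values_separated_at_k2(self):
        m = PropertyMapping("t", {"A": 0.0, "C": 0.0, "D": 4.0})
        out = mp.simplify_linear(m, 2)
        assert out.table == {"A": 0, "C": 0, "D": 1}

    def test_degenerate_range_rejected(self):
        m = PropertyMapping("t", {"A": 1.0, "C": 1.0})
        with pytest.raises(ValueError, match="degenerate"):
            mp.simplify_linear(m, 2)


class TestSimplifyKmeans:
    def test_matches_exhaustive_two_partition_oracle(self):
        values = {"A": 0.0, "C": 0.1, "D": 5.0, "E": 5.1}
        m = PropertyMapping("t", values)
        out = mp.simplify_kmeans(m, 2, seed=11)
        low, high = best_two_partition_1d(values.values())
        for symbol, v in values.items():
            assert out.table[symbol] == (0 if v in low else 1)

    def test_k_equals_distinct_values_gives_one_class_each(self):
        m = PropertyMapping("t", {"A": 0.0, "C": 2.0, "D": 9.0})
        out = mp.simplify_kmeans(m, 3, seed=0)
        assert sorted(out.table.values()) == [0, 1, 2]
        assert out.table["A"] < out.table["C"] < out.table["D"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 99])
    def test_seed_invariant_on_well_separated_values(self, seed):
        m = PropertyMapping("t", {"A": 0.0, "C": 0.2, "D": 10.0, "E": 10.3})
        out = mp.simplify_kmeans(m, 2, seed=seed)
        assert out.table == {"A": 0, "C": 0, "D": 1, "E": 1}

    def test_equal_values_get_equal_classes(self):
        m = PropertyMapping("t", {"A": 1.0, "C": 1.0, "D": 8.0})
        out = mp.simplify_kmeans(m, 2, seed=5)
        assert out.table["A"] == out.table["C"] != out.table["D"]

    def test_k_above_distinct_values_rejected(self):
        m = PropertyMapping("t", {"A": 1.0, "C": 1.0, "D": 8.0})
        with pytest.raises(ValueError):
            mp.simplify_kmeans(m, 3, seed=0)


def test_normalized_rescales_onto_unit_interval():
    hydro = mp.load_predefined("hydropathy")
    norm = hydro.normalized(lo=-4.5, hi=4.5)
    assert norm["I"] == pytest.approx(1.0)   # KD max 4.5
    assert norm["R"] == pytest.approx(0.0)   # KD min -4.5
    assert norm["G"] == pytest.approx((-0.4 + 4.5) / 9)
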