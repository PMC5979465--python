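"""Record parsing, unit harmonization, labelling and curation rules."""

import io
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protstab import dataset
from protstab.dataset import (CurationConfig, VariantRecord, apply_curation,
                              harmonize_units, label_stability,
                              make_reverse_variants, parse_records,
                              select_representative, validate_sequence)

HEADER = ("record_id\tprotein_id\tsequence_ref\twt_aa\tposition\tmut_aa"
          "\tddg\tddg_unit\ttemperature\tph")


def _file(rows):
    return io.StringIO(HEADER + "\n" + "\n".join(rows) + "\n")


def rec(**kw) -> VariantRecord:
    base = dict(record_id="r1", protein_id="P1", sequence_ref="P1",
                wt_aa="A", position=5, mut_aa="V", ddg=1.0)
    base.update(kw)
    return VariantRecord(**base)


class TestParsing:
    def test_toy_file_with_kj_row(self):
        out = parse_records(_file([
            "r1\tP1\tP1\tA\t3\tV\t1.0\tkcal/mol\t25\t7.0",
            "r2\tP1\tP1\tK\t8\tE\t4.184\tkJ/mol\t25\t7.0",
            "r3\tP2\tP2\tL\t2\tF\t-2.0\tkcal/mol\t25\t6.5",
        ]))
        assert len(out.records) == 3 and not out.errors
        kj = [r for r in out.records if r.ddg_unit_raw == "kJ/mol"]
        assert len(kj) == 1 and harmonize_units(kj[0]).ddg == pytest.approx(1.0)

    def test_invalid_rows_reported_not_dropped(self):
        out = parse_records(_file([
            "r1\tP1\tP1\tA\t0\tV\t1.0\tkcal/mol\t25\t7.0",   # position 0
            "r2\tP1\tP1\tB\t3\tV\t1.0\tkcal/mol\t25\t7.0",   # bad residue
            "r3\tP1\tP1\tA\t3\tV\t1.0\tkcal/mol\t25\t7.0",
        ]))
        assert [r.record_id for r in out.records] == ["r3"]
        assert sorted(e.record_id for e in out.errors) == ["r1", "r2"]

    def test_missing_mandatory_column_is_hard_error(self):
        bad = io.StringIO("record_id\tprotein_id\nx\ty\n")
        with pytest.raises(ValueError, match="wt_aa|sequence_ref"):
            parse_records(bad)

    def test_fixture_roundtrip_with_duplicates(self, tmp_path):
        from protstab.synthetic_fixtures import (
            generate_corrupted_protherm_file)
        frame, _, truth = generate_corrupted_protherm_file(
            10, {"duplicate": 2}, seed=11)
        path = tmp_path / "records.tsv"
        frame.to_csv(path, sep="\t", index=False)
        out = parse_records(path)
        assert len(out.records) == 12 and not out.errors


class TestHarmonization:
    @pytest.mark.parametrize("ddg_kj,expected", [(4.184, 1.0),
                                                 (-8.368, -2.0)])
    def test_kj_conversion(self, ddg_kj, expected):
        r = harmonize_units(rec(ddg=ddg_kj, ddg_unit_raw="kJ/mol"))
        assert r.ddg == pytest.approx(expected)
        assert r.ddg_unit_raw == "kcal/mol"

    def test_kelvin_temperature(self):
        r = harmonize_units(rec(temperature_c=298.15))
        assert r.temperature_c == pytest.approx(25.0)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            harmonize_units(rec(ddg_unit_raw="J/mol"))

    @given(ddg=st.floats(-20, 20), kelvin=st.booleans(),
           temp=st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, ddg, kelvin, temp):
        r = rec(ddg=ddg, ddg_unit_raw="kJ/mol",
                temperature_c=temp + 273.15 if kelvin else temp)
        once = harmonize_units(r)
        assert harmonize_units(once) == once


class TestLabelling:
    @pytest.mark.parametrize("ddg,label", [
        (0.3, "no_effect"), (-2.0, "decrease"), (0.5, "no_effect"),
        (-0.5, "no_effect"), (0.51, "increase"), (17.0, "increase"),
    ])
    def test_examples(self, ddg, label):
        assert label_stability(ddg) == label

    @given(ddg=st.floats(-17.4, 23.0))
    @settings(max_examples=200, deadline=None)
    def test_partition_and_mirror(self, ddg):
        label = label_stability(ddg)
        assert label in ("increase", "no_effect", "decrease")
        if abs(ddg) > 0.5:
            mirror = {"increase": "decrease", "decrease": "increase"}
            assert label_stability(-ddg) == mirror[label]


class TestSequenceValidation:
    def test_match(self):
        ok, why = validate_sequence(rec(wt_aa="K", position=2, mut_aa="E"),
                                    "MKV")
        assert ok and why == "match"

    def test_shift_candidate(self):
        ok, why = validate_sequence(rec(wt_aa="V", position=2, mut_aa="A"),
                                    "MKV")
        assert not ok and why == "shift_candidate offset +1"

    def test_out_of_range(self):
        ok, why = validate_sequence(rec(position=9), "MKV")
        assert not ok and why == "out_of_range"

    def test_background_applied_before_check(self):
        # pseudo-wild-type carrying C54T: the variant at 54 is checked
        # against T, not against the untouched reference C
        seq = "A" * 53 + "C" + "A" * 46
        r = rec(wt_aa="T", position=54, mut_aa="S",
                background_variants=(("C", 54, "T"),))
        ok, why = validate_sequence(r, seq)
        assert ok
        ok, _ = validate_sequence(rec(wt_aa="C", position=54, mut_aa="S"),
                                  seq)
        assert ok  # and without the background the raw C matches


class TestCuration:
    def test_out_of_range_ph_superseded_only_when_alternative_exists(self):
        a = rec(record_id="a", ph=3.0)
        b = rec(record_id="b", ph=7.0, ddg=1.2)
        curated, report = apply_curation([a, b])
        assert [r.record_id for r in curated] == ["b"]
        assert ("a", dataset.REASON_PH) in [(i, c) for i, c, _ in
                                            report.rejected]
        # singleton at pH 4 with no alternative: kept
        curated, report = apply_curation([rec(record_id="c", ph=4.0)])
        assert report.kept == ["c"] and not report.rejected

    def test_report_partitions_input(self):
        records = [rec(record_id=f"r{i}", position=i + 1,
                       wt_aa="A", mut_aa="V") for i in range(4)]
        records[2] = replace(records[2], state_flag="unfolded")
        curated, report = apply_curation(records)
        all_ids = {r.record_id for r in records}
        assert set(report.kept) | report.rejected_ids() == all_ids
        assert set(report.kept) & report.rejected_ids() == set()
        assert {r.record_id for r in curated} == set(report.kept)

    def test_planted_corruption_rejected_with_planted_reasons(self):
        from protstab.synthetic_fixtures import (
            generate_corrupted_protherm_file)
        frame, seqs, truth = generate_corrupted_protherm_file(
            12, {"kj": 2, "kelvin": 1, "duplicate": 2, "unfolded": 1,
                 "stage": 1, "ph": 1, "salt": 1, "non_preferred": 1,
                 "short_peptide": 1}, seed=4)
        buf = io.StringIO()
        frame.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        parsed = parse_records(buf)
        assert not parsed.errors
        harmonized = [harmonize_units(r) for r in parsed.records]
        _, report = apply_curation(harmonized, sequences=seqs)
        got = {rid: reason for rid, reason, _ in report.rejected}
        expected = {t.record_id: t.reason for t in truth.itertuples()
                    if t.disposition == "rejected"}
        assert got == expected
        assert set(report.kept) == set(
            truth[truth.disposition == "kept"].record_id)


class TestRepresentative:
    def test_calorimetry_preferred(self):
        dsc = rec(record_id="a", method="DSC", ph=6.0)
        chem = rec(record_id="b", method="chemical_denaturation", ph=7.0)
        assert select_representative([dsc, chem]).record_id == "a"

    def test_ph_closest_to_seven(self):
        r1 = rec(record_id="a", method="thermal_other", ph=8.5)
        r2 = rec(record_id="b", method="thermal_other", ph=6.5)
        assert select_representative([r1, r2]).record_id == "b"

    def test_tie_break_by_record_id(self):
        r1 = rec(record_id="z")
        r2 = rec(record_id="a")
        assert select_representative([r1, r2]).record_id == "a"

    def test_empty_input(self):
        with pytest.raises(ValueError):
            select_representative([])


class TestReverseVariants:
    def test_mirror_definition_and_cardinality(self):
        records = [rec(record_id="a", ddg=1.2),
                   rec(record_id="b", wt_aa="K", mut_aa="E", ddg=0.2)]
        out, _ = make_reverse_variants(records)
        assert len(out) == 4
        mirror = next(r for r in out if r.record_id == "a_rev")
        assert (mirror.wt_aa, mirror.mut_aa) == ("V", "A")
        assert mirror.ddg == -1.2 and mirror.is_reverse
        neutral = next(r for r in out if r.record_id == "b_rev")
        assert label_stability(neutral.ddg) == "no_effect"

    def test_double_mirror_is_involution(self):
        records = [rec(record_id="a", ddg=2.5),
                   rec(record_id="b", wt_aa="F", mut_aa="W", ddg=-1.0)]
        out, _ = make_reverse_variants(records)
        mirrors = [r for r in out if r.is_reverse]
        back, _ = make_reverse_variants(mirrors)
        originals = {(r.wt_aa, r.mut_aa, r.ddg) for r in records}
        restored = {(r.wt_aa, r.mut_aa, r.ddg) for r in back
                    if r.record_id.endswith("_rev_rev")}
        assert restored == originals

    def test_mutated_reference_sequence_emitted(self):
        records = [rec(record_id="a", wt_aa="M", position=1, mut_aa="L")]
        out, seqs = make_reverse_variants(records, {"P1": "MKV"})
        assert seqs == {"P1|M1L": "LKV"}
        assert out[1].sequence_ref == "P1|M1L"


class TestConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            CurationConfig(ph_min=9, ph_max=5)
        with pytest.raises(ValueError):
            CurationConfig(neutral_halfwidth=0)

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            rec(wt_aa="A", mut_aa="A")
        with pytest.raises(ValueError):
            rec(position=0)
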