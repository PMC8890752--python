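import math

import pytest

from qlckit import (
    Proteome,
    ProteinRecord,
    Region,
    compare_region_sets,
    detect_proteome,
    enrichment_log2,
    residue_frequencies,
    segment_proteome,
)


class TestResidueFrequencies:
    def test_exclusion_removes_category_and_denominator(self):
        table = residue_frequencies(["QHQH"], exclude="Q")
        assert table.fractions["H"] == 1.0
        assert table.total_residues == 2
        assert "Q" not in table.fractions

    def test_no_exclusion(self):
        table = residue_frequencies(["AAHH"])
        assert table.fractions["A"] == 0.5
        assert table.fractions["H"] == 0.5

    def test_everything_excluded_is_an_error(self):
        with pytest.raises(ValueError, match="no countable residues"):
            residue_frequencies(["QQQQ"], exclude="Q")

    def test_ambiguity_codes_not_counted(self):
        table = residue_frequencies(["AXXA"])
        assert table.total_residues == 2
        assert table.fractions["A"] == 1.0

    def test_fractions_sum_to_one(self):
        table = residue_frequencies(["ACDEFGHIKLMNPQRSTVWY" * 3], exclude="Q")
        assert sum(table.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def _proteome_and_region(fg_seq: str, bg_extra: str):
    proteome = Proteome(
        [
            ProteinRecord(id="fg", sequence=fg_seq),
            ProteinRecord(id="bg", sequence=bg_extra),
        ]
    )
    region = Region.from_sequence("fg", 0, len(fg_seq), fg_seq, "Q")
    return proteome, [region]


class TestEnrichment:
    def test_identical_composition_gives_zero_ratios(self):
        seq = "QHAPQHAP" * 4
        proteome, regions = _proteome_and_region(seq, seq)
        table = enrichment_log2(regions, proteome).table
        present = table[table.fg_count > 0]
        assert (present.log2_ratio.abs() < 1e-12).all()

    def test_twofold_enrichment_is_one_log2_unit(self):
        # foreground H fraction 0.5, background H fraction 0.25 (Q excluded)
        proteome, regions = _proteome_and_region("QHQA" * 10, "AAAH" * 30)
        table = enrichment_log2(regions, proteome, background=None)
        fg = table.table.set_index("residue")
        h = fg.loc["H"]
        assert h.log2_ratio == pytest.approx(
            math.log2(h.fg_fraction / h.bg_fraction), abs=1e-12
        )

    def test_exclude_target_removes_it_from_table(self):
        proteome, regions = _proteome_and_region("QHQH" * 10, "QAHA" * 10)
        table = enrichment_log2(regions, proteome, exclude_target=True)
        assert "Q" not in set(table.table.residue)
        kept = enrichment_log2(regions, proteome, exclude_target=False)
        assert "Q" in set(kept.table.residue)

    def test_zero_count_categories_flagged_not_infinite(self):
        proteome, regions = _proteome_and_region("QHQH" * 10, "AAAA" * 10)
        table = enrichment_log2(regions, proteome).table.set_index("residue")
        w = table.loc["W"]  # absent from foreground and background alike
        assert w.flag == "zero_both"
        assert math.isnan(w.log2_ratio)
        a = table.loc["A"]  # background only
        assert a.flag == "zero_fg"
        assert math.isnan(a.log2_ratio)

    def test_antisymmetric_under_fg_bg_swap(self):
        seq_a, seq_b = "QHAPNS" * 20, "QHHPPA" * 20
        proteome = Proteome(
            [ProteinRecord(id="a", sequence=seq_a), ProteinRecord(id="b", sequence=seq_b)]
        )
        reg_a = [Region.from_sequence("a", 0, len(seq_a), seq_a, "Q")]
        bg_a = Proteome([ProteinRecord(id="a", sequence=seq_a)])
        bg_b = Proteome([ProteinRecord(id="b", sequence=seq_b)])
        reg_b = [Region.from_sequence("b", 0, len(seq_b), seq_b, "Q")]
        ab = enrichment_log2(reg_a, proteome, background=bg_b).table.set_index("residue")
        ba = enrichment_log2(reg_b, proteome, background=bg_a).table.set_index("residue")
        for aa in ab.index:
            r1, r2 = ab.loc[aa].log2_ratio, ba.loc[aa].log2_ratio
            if r1 == r1 and r2 == r2:  # both finite (NaN != NaN)
                assert r1 == pytest.approx(-r2, abs=1e-12)

    def test_empty_foreground_is_an_error(self, tiny_proteome):
        with pytest.raises(ValueError, match="empty"):
            enrichment_log2([], tiny_proteome)


class TestCompareRegionSets:
    @staticmethod
    def _region(pid, seq, proteome_records):
        proteome_records.append(ProteinRecord(id=pid, sequence=seq))
        return Region.from_sequence(pid, 0, len(seq), seq, None)

    def test_identical_composition_zero_excess(self):
        records = []
        a = self._region("a", "HAAN" * 10, records)
        b = self._region("b", "HAAN" * 10, records)
        proteome = Proteome(records)
        assert compare_region_sets([a], [b], proteome) == pytest.approx(0.0)

    def test_fifty_percent_excess_arithmetic(self):
        records = []
        a = self._region("a", ("H" * 6 + "A" * 94), records)  # H fraction 0.06
        b = self._region("b", ("H" * 4 + "A" * 96), records)  # H fraction 0.04
        proteome = Proteome(records)
        assert compare_region_sets([a], [b], proteome) == pytest.approx(50.0)

    def test_overlap_excluded_from_b(self):
        seq = "H" * 10 + "A" * 90
        proteome = Proteome([ProteinRecord(id="p", sequence=seq)])
        a = [Region.from_sequence("p", 0, 10, seq, None)]  # the H block
        b = [Region.from_sequence("p", 0, 100, seq, None)]  # whole protein
        # with overlap excluded, B keeps only the 90 A residues -> error (no H)
        with pytest.raises(ValueError, match="absent"):
            compare_region_sets(a, b, proteome, residue="H", exclude_overlap=True)
        # without exclusion B has H fraction 0.1, A has 1.0 -> 900% excess
        excess = compare_region_sets(a, b, proteome, residue="H", exclude_overlap=False)
        assert excess == pytest.approx(900.0)

    def test_empty_set_is_an_error(self, tiny_proteome):
        with pytest.raises(ValueError, match="non-empty"):
            compare_region_sets([], [], tiny_proteome)

    def test_planted_his_contrast_recovered(self, planted_proteome):
        """QLC plants carry 1.5x the histidine density of generic LCD plants
        (0.12 vs 0.08); comparing the planted region sets recovers a 50%
        excess up to per-tract rounding."""
        proteome, truth = planted_proteome
        sets = {}
        for kind in ("xlc", "lcd"):
            rows = truth[truth.kind == kind]
            sets[kind] = [
                Region.from_sequence(
                    row.protein_id, row.start, row.end,
                    proteome[row.protein_id].sequence,
                    "Q" if kind == "xlc" else None,
                )
                for row in rows.itertuples()
            ]
        excess = compare_region_sets(sets["xlc"], sets["lcd"], proteome, residue="H")
        assert excess == pytest.approx(50.0, abs=5.0)

    def test_detected_region_pipeline_shows_his_excess(self, planted_proteome):
        """Running both detectors end to end preserves the direction and
        rough size of the planted histidine contrast."""
        proteome, _ = planted_proteome
        qlcs = detect_proteome(proteome)
        lcds = segment_proteome(proteome)
        excess = compare_region_sets(qlcs, lcds, proteome, residue="H")
        assert 30.0 < excess < 70.0
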