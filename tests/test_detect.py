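import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qlckit import (
    LCParams,
    Proteome,
    ProteinRecord,
    Region,
    detect_proteome,
    detect_xlc,
    rank_regions,
    sweep_max_gap,
)

from oracles import brute_force_xlc

DEFAULTS = LCParams()


def spans(regions):
    return [(r.start, r.end) for r in regions]


class TestDetectXlc:
    def test_minimal_qualifying_homopolymer(self):
        regions = detect_xlc("Q" * 15)
        assert spans(regions) == [(0, 15)]
        assert regions[0].fraction_target == 1.0

    def test_min_length_boundary(self):
        assert detect_xlc("Q" * 14) == []

    def test_two_blocks_bridged_by_short_gap(self):
        regions = detect_xlc("QQQQ" + "A" * 12 + "QQQQ")
        assert spans(regions) == [(0, 20)]
        assert regions[0].n_target == 8
        assert regions[0].fraction_target == pytest.approx(0.40)

    def test_gap_of_exactly_max_gap_is_allowed(self):
        regions = detect_xlc("QQQQQQ" + "A" * 17 + "QQQQQQ")
        assert spans(regions) == [(0, 29)]
        assert regions[0].fraction_target == pytest.approx(12 / 29)

    def test_gap_beyond_max_gap_splits_the_chain(self):
        assert detect_xlc("QQQQ" + "A" * 18 + "QQQQ") == []

    def test_regions_start_and_end_on_target(self):
        regions = detect_xlc("AAA" + "Q" * 15 + "AAA" + "Q" * 16 + "AAA", LCParams(max_gap=2))
        for r, seq in zip(regions, ["AAA" + "Q" * 15 + "AAA" + "Q" * 16 + "AAA"] * 2):
            assert seq[r.start] == "Q" and seq[r.end - 1] == "Q"

    def test_invalid_target_residue(self):
        with pytest.raises(ValueError, match="target residue"):
            LCParams(target_residue="J")

    def test_other_target_residue(self):
        regions = detect_xlc("N" * 15, LCParams(target_residue="N"))
        assert spans(regions) == [(0, 15)]

    def test_ambiguity_codes_count_as_non_target(self):
        # X never matches Q: it behaves exactly like any other interruption
        assert spans(detect_xlc("QQQQ" + "X" * 12 + "QQQQ")) == [(0, 20)]
        assert detect_xlc("QQQQ" + "X" * 18 + "QQQQ") == []

    @pytest.mark.parametrize("n_flank", [1, 5, 30])
    def test_flank_invariance(self, n_flank):
        core = "QQQAAQQQAAAQQQQ"
        base = detect_xlc(core)
        padded = detect_xlc("A" * n_flank + core + "A" * n_flank)
        assert spans(padded) == [(s + n_flank, e + n_flank) for s, e in spans(base)]

    def test_oracle_equivalence_seeded_sample(self):
        """Detector output equals exhaustive substring enumeration on random
        sequences over {Q, A, H}."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            length = int(rng.integers(1, 61))
            seq = "".join(rng.choice(list("QAH"), size=length))
            assert spans(detect_xlc(seq)) == brute_force_xlc(seq), seq

    @given(st.text(alphabet="QAH", min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_soundness_every_region_passes_all_criteria(self, seq):
        for r in detect_xlc(seq):
            sub = seq[r.start : r.end]
            assert sub[0] == "Q" and sub[-1] == "Q"
            assert r.length >= DEFAULTS.min_length
            assert r.fraction_target >= DEFAULTS.min_fraction
            runs = [len(run) for run in sub.split("Q") if run]
            assert not runs or max(runs) <= DEFAULTS.max_gap

    @given(st.text(alphabet="QA", min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_min_fraction(self, seq):
        loose = sum(r.length for r in detect_xlc(seq, LCParams(min_fraction=0.25)))
        tight = sum(r.length for r in detect_xlc(seq, LCParams(min_fraction=0.5)))
        assert tight <= loose


class TestDetectProteome:
    def test_tags_protein_ids_in_order(self):
        proteome = Proteome(
            [ProteinRecord(id="a", sequence="Q" * 20), ProteinRecord(id="b", sequence="Q" * 20)]
        )
        regions = detect_proteome(proteome)
        assert [(r.protein_id, r.start, r.end) for r in regions] == [("a", 0, 20), ("b", 0, 20)]

    def test_empty_proteome(self):
        assert detect_proteome(Proteome([])) == []

    def test_planted_tracts_recovered(self, planted_proteome):
        proteome, truth = planted_proteome
        regions = detect_proteome(proteome)
        planted = truth[truth.kind == "xlc"]
        assert len(regions) == len(planted)
        by_protein = {r.protein_id: r for r in regions}
        for row in planted.itertuples():
            detected = by_protein[row.protein_id]
            planted_region = Region.from_sequence(
                row.protein_id, row.start, row.end,
                proteome[row.protein_id].sequence, "Q",
            )
            assert detected.jaccard(planted_region) >= 0.9


class TestSweep:
    def test_single_gap_matches_detect_proteome(self, planted_proteome):
        proteome, _ = planted_proteome
        rows, report = sweep_max_gap(proteome, DEFAULTS, [17])
        regions = detect_proteome(proteome)
        assert rows[0].n_regions == len(regions)
        assert rows[0].n_residues == sum(r.length for r in regions)
        assert report.best_gap_by_regions == 17

    def test_empty_proteome_all_zero(self):
        rows, _ = sweep_max_gap(Proteome([]), DEFAULTS, [1, 2, 3])
        assert [(r.max_gap, r.n_regions, r.n_residues) for r in rows] == [
            (1, 0, 0), (2, 0, 0), (3, 0, 0)
        ]

    def test_argmax_at_smallest_sufficient_gap(self):
        """Tracts whose interruptions are all exactly 10 residues, between
        target blocks too short to stand alone, inside target-free flanks:
        both sweep statistics are maximized at the smallest swept gap >= 10."""
        from qlckit import PlantSpec, generate_proteome

        spec = PlantSpec(
            kind="xlc", n_tracts=30, tract_length=(40, 80),
            target_fraction=0.4, max_gap=10, gap_mode="exact",
        )
        proteome, _ = generate_proteome(30, plants=spec, seed=7)
        _, report = sweep_max_gap(proteome, DEFAULTS, list(range(1, 31)))
        assert report.best_gap_by_regions == 10
        assert report.best_gap_by_residues == 10

    def test_empty_gap_list_rejected(self, tiny_proteome):
        with pytest.raises(ValueError):
            sweep_max_gap(tiny_proteome, DEFAULTS, [])


class TestRank:
    @staticmethod
    def _region(pid, n_his, length=20):
        seq = "H" * n_his + "Q" * (length - n_his)
        return Region.from_sequence(pid, 0, length, seq, "Q")

    def test_descending_ranks(self):
        regions = [self._region("a", 5), self._region("b", 2), self._region("c", 7)]
        ranked = rank_regions(regions, key="n_his")
        assert [(rank, r.protein_id) for rank, r in ranked] == [(1, "c"), (2, "a"), (3, "b")]

    def test_ties_share_better_rank_ordered_by_protein_id(self):
        regions = [self._region("b", 4), self._region("a", 4), self._region("c", 9)]
        ranked = rank_regions(regions, key="n_his")
        assert [(rank, r.protein_id) for rank, r in ranked] == [(1, "c"), (2, "a"), (2, "b")]

    def test_empty_input(self):
        assert rank_regions([], key="length") == []

    def test_unknown_key(self):
        with pytest.raises(ValueError, match="unknown rank key"):
            rank_regions([], key="volume")
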