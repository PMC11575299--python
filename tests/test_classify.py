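"""Segment-path construction and seven-category classification, including
truth recovery on simulated molecules and the ratio tables."""

import numpy as np
import pytest

from aavrep import (
    CATEGORY_NAMES,
    AlignmentHit,
    ReadHitSet,
    builtin_local_hits,
    category_ratios,
    classify,
    classify_rca_shape,
    filter_and_select,
    make_circular_and_rca,
    make_molecule,
    normalize_per_mito,
    segments_from_hits,
)
from aavrep.classify import CategoryCall


def _hit(read_id="r", q=(0, 100), s=(0, 100), strand="+", score=150.0):
    return AlignmentHit(read_id, "ref", q[0], q[1], s[0], s[1], strand,
                        99.0, q[1] - q[0], 1, 0, 1e-30, score)


def _path_for(genome, sequence, read_id="r"):
    hits = builtin_local_hits(read_id, sequence, genome.sequence)
    (hs,) = filter_and_select(hits)
    return segments_from_hits(hs)


def _classify_seq(genome, sequence):
    path = _path_for(genome, sequence)
    return classify(path, genome.total_len, genome.itr_intervals)


class TestSegments:
    def test_duplicate_hits_merge_to_one_segment(self):
        hs = ReadHitSet("r", [_hit(), _hit()], 200, True)
        path = segments_from_hits(hs)
        assert len(path.segments) == 1

    def test_out_of_order_hits_sorted_by_read_position(self):
        hs = ReadHitSet("r", [_hit(q=(500, 700), s=(0, 200)),
                              _hit(q=(0, 200), s=(300, 500))], 400, True)
        path = segments_from_hits(hs)
        assert [s.q_start for s in path.segments] == [0, 500]

    def test_staircase_preserved(self):
        """Three abutting same-strand hits with subject wrap-around stay
        three segments."""
        hs = ReadHitSet("r", [
            _hit(q=(0, 4000), s=(700, 4700)),
            _hit(q=(4000, 8700), s=(0, 4700)),
            _hit(q=(8700, 12000), s=(0, 3300)),
        ], 12000, True)
        path = segments_from_hits(hs)
        assert len(path.segments) == 3

    def test_empty_hit_set_is_an_error(self):
        with pytest.raises(ValueError, match="no retained hits"):
            segments_from_hits(ReadHitSet("r", []))


class TestClassifyRules:
    def test_monomer(self, genome, rng):
        m = make_molecule(genome, 1, rng)
        assert _classify_seq(genome, m.sequence).category == 1

    def test_head_to_tail_triplet(self, genome, rng):
        m = make_molecule(genome, 3, rng, unit_count=3)
        call = _classify_seq(genome, m.sequence)
        assert call.category == 3
        assert all(j == "HT" for j in call.junction_labels)

    def test_itr_array(self, genome, rng):
        m = make_molecule(genome, 6, rng, unit_count=25)
        call = _classify_seq(genome, m.sequence)
        assert call.category == 6 and call.itr_only

    def test_snapback_falls_through_to_others(self, genome, rng):
        m = make_molecule(genome, 7, rng, subkind="snapback")
        assert _classify_seq(genome, m.sequence).category == 7

    def test_two_unit_foldback_is_duplex_not_alternating(self, genome, rng):
        m = make_molecule(genome, 4, rng, unit_count=2)
        assert _classify_seq(genome, m.sequence).category == 2


class TestTruthRecovery:
    @pytest.mark.parametrize("category", range(1, 8))
    def test_noise_free_recovery_per_category(self, genome, category):
        """Noise-free whole-molecule reads of every category are recovered
        exactly (10 molecules per category here; the full 50-molecule panel
        runs in the acceptance suite)."""
        for i in range(10):
            rng = np.random.default_rng(7000 + 97 * category + i)
            m = make_molecule(genome, category, rng)
            call = _classify_seq(genome, m.sequence)
            assert call.category == category, (category, i, call)


class TestRcaShapes:
    def test_circular_monomer_parallel(self, genome, rng):
        m = make_circular_and_rca(genome, 1, "HT", 4, rng, enzyme="HindIII")
        path = _path_for(genome, m.sequence)
        assert classify_rca_shape(path, genome.total_len) == "parallel"

    def test_alternating_circle_v_shape(self, genome, rng):
        m = make_circular_and_rca(genome, 2, "alternating", 3, rng,
                                  enzyme="HindIII")
        path = _path_for(genome, m.sequence)
        assert classify_rca_shape(path, genome.total_len) == "V"

    def test_single_segment_degenerate_parallel(self):
        from aavrep.classify import SegmentPath, Segment

        path = SegmentPath("r", [Segment(0, 4000, 700, 4700, "+")], 4000)
        assert classify_rca_shape(path, 4700) == "parallel"


class TestRatios:
    def test_ratio_table_layout_and_sum(self):
        counts = {1: 33, 2: 26, 3: 11, 4: 2, 5: 2, 6: 2, 7: 24}
        calls = [CategoryCall(f"r{i}_{c}", c, 1, 1, (), False)
                 for c, n in counts.items() for i in range(n)]
        table = category_ratios(calls)
        assert table.loc[0, "Monomer"] == pytest.approx(0.33)
        assert table.loc[0, "Duplex"] == pytest.approx(0.26)
        assert table.loc[0, "ITR repeats"] == pytest.approx(0.02)
        total = sum(table.loc[0, CATEGORY_NAMES[k]] for k in range(1, 8))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_category_present_as_zero(self):
        calls = [CategoryCall("r", 1, 1, 1, (), False)]
        table = category_ratios(calls)
        assert table.loc[0, "Others"] == 0.0

    def test_normalize_per_mito(self):
        assert normalize_per_mito(3, 5000) == pytest.approx(6.0)
        with pytest.raises(ValueError):
            normalize_per_mito(3, 0)

    def test_normalization_is_linear_in_count(self):
        assert normalize_per_mito(30, 5000) == pytest.approx(
            10 * normalize_per_mito(3, 5000))
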