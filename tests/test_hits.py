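"""Hit layer: BLAST tabular round trips, the built-in aligner against a
Smith-Waterman oracle, and the e-value / hit-sum selection rule."""

import numpy as np
import pytest

from aavrep import (
    AlignmentHit,
    builtin_local_hits,
    filter_and_select,
    parse_blast_tab,
    revcomp,
    write_blast_tab,
)
from helpers import smith_waterman


def _hit(read_id="r1", q=(0, 100), s=(0, 100), strand="+", e=1e-20,
         alen=None, score=150.0):
    return AlignmentHit(read_id, "ref", q[0], q[1], s[0], s[1], strand,
                        98.0, alen or (q[1] - q[0]), 2, 0, e, score)


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestBlastTab:
    def test_minus_strand_coordinates(self):
        row = "r1\tref\t97.500\t51\t1\t0\t1\t51\t100\t50\t1e-20\t90.1\n"
        (h,) = parse_blast_tab([row])
        assert h.strand == "-"
        assert (h.s_start, h.s_end) == (49, 100)
        assert (h.q_start, h.q_end) == (0, 51)

    def test_write_then_parse_round_trip(self, tmp_path):
        hits = [_hit(), _hit(q=(10, 260), s=(40, 290), strand="-", e=0.05)]
        path = tmp_path / "hits.tsv"
        write_blast_tab(hits, path)
        assert parse_blast_tab(path) == hits

    def test_zero_length_alignment_rejected(self):
        row = "r1\tref\t100.000\t0\t0\t0\t5\t4\t10\t9\t1e-5\t10.0\n"
        with pytest.raises(ValueError, match="line 1"):
            parse_blast_tab([row])

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="12 columns"):
            parse_blast_tab(["a\tb\tc\n"])


class TestBuiltinAligner:
    def test_identical_read_single_full_hit(self, genome):
        hits = builtin_local_hits("r", genome.sequence, genome.sequence)
        full = [h for h in hits if h.q_span >= genome.total_len - 5]
        assert len(full) == 1 and full[0].strand == "+"
        assert (full[0].q_start, full[0].q_end) == (0, genome.total_len)
        assert full[0].percent_identity == 100.0

    def test_half_forward_half_reverse(self, genome):
        """left half + revcomp(right half) gives two adjoining hits on
        opposite strands."""
        ref = genome.sequence
        mid = len(ref) // 2
        read = ref[:mid] + revcomp(ref[mid:])
        hits = builtin_local_hits("r", read, ref)
        big = sorted([h for h in hits if h.q_span > 1000],
                     key=lambda h: h.q_start)
        assert [h.strand for h in big] == ["+", "-"]
        assert abs(big[0].q_end - big[1].q_start) <= 30

    def test_unrelated_read_has_no_hits(self, genome):
        """Random 1-kb reads unrelated to the reference yield no hits at
        the 100-nt minimum (100 seeded draws)."""
        total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            read = _random_dna(rng, 1000)
            total += len(builtin_local_hits("r", read, genome.sequence))
        assert total == 0

    def test_read_shorter_than_k_empty(self, genome):
        assert builtin_local_hits("r", "ACGT", genome.sequence) == []

    @pytest.mark.parametrize("case_seed", range(25))
    def test_matches_smith_waterman_on_toys(self, case_seed):
        """On 300-nt toys with an implanted, lightly mutated reference
        segment, the built-in hit interval matches the Smith-Waterman local
        optimum within +/-2 nt per end."""
        rng = np.random.default_rng(case_seed)
        ref = _random_dna(rng, 300)
        seg = list(ref[75:225])
        for _ in range(3):  # substitutions away from the segment edges
            pos = int(rng.integers(10, len(seg) - 10))
            seg[pos] = "ACGT"[(("ACGT".index(seg[pos])) + 1) % 4]
        read = _random_dna(rng, 100) + "".join(seg) + _random_dna(rng, 50)
        hits = builtin_local_hits("r", read, ref, min_hit_len=100)
        assert hits, "no hit found for implanted segment"
        h = max(hits, key=lambda h: h.q_span)
        _, (q0, q1), (s0, s1) = smith_waterman(read, ref)
        assert abs(h.q_start - q0) <= 2 and abs(h.q_end - q1) <= 2
        assert abs(h.s_start - s0) <= 2 and abs(h.s_end - s1) <= 2


class TestFilterAndSelect:
    def test_e_value_filter_is_strict_greater(self):
        """e-values {0.05, 0.1, 0.2}: 0.1 is kept, 0.2 removed."""
        hits = [_hit(e=0.05), _hit(q=(200, 300), s=(200, 300), e=0.1),
                _hit(q=(400, 500), s=(400, 500), e=0.2)]
        (rs,) = filter_and_select(hits, sum_threshold=3000)
        assert sorted(h.e_value for h in rs.hits) == [0.05, 0.1]

    def test_sum_threshold_is_strict_greater(self):
        hits_a = [_hit("ra", q=(0, 2000), s=(0, 2000)),
                  _hit("ra", q=(2100, 3600), s=(0, 1500))]
        hits_b = [_hit("rb", q=(0, 3000), s=(0, 3000))]
        sets = {rs.read_id: rs for rs in
                filter_and_select(hits_a + hits_b, sum_threshold=3000)}
        assert sets["ra"].hit_sum == 3500 and sets["ra"].selected
        assert sets["rb"].hit_sum == 3000 and not sets["rb"].selected

    def test_read_with_no_retained_hits_rejected(self):
        (rs,) = filter_and_select([_hit(e=5.0)])
        assert rs.hit_sum == 0 and not rs.selected

    def test_idempotent(self):
        hits = [_hit(e=0.05), _hit(q=(200, 300), s=(200, 300), e=0.02)]
        once = filter_and_select(hits)
        twice = filter_and_select([h for rs in once for h in rs.hits])
        assert [(rs.read_id, rs.hit_sum, rs.selected) for rs in once] == \
               [(rs.read_id, rs.hit_sum, rs.selected) for rs in twice]
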