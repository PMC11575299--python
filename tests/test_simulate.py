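"""Molecule construction truth labels, length conservation, the error
model's statistics, and reproducibility of the read simulator."""

import numpy as np
import pytest

from aavrep import SimConfig, make_circular_and_rca, make_molecule
from aavrep.simulate import (
    mutate_sequence,
    simulate_molecules,
    simulate_reads,
    truth_table,
    write_reads_fastq,
)
from helpers import mismatch_fraction


class TestMakeMolecule:
    def test_head_to_tail_truth_labels(self, genome, rng):
        m = make_molecule(genome, 3, rng, unit_count=3)
        assert m.unit_strands == ("+", "+", "+")
        assert m.junction_types == ("TRT", "TRT")
        assert len(set(m.itr_orientations)) == 1

    def test_alternating_two_units_strands(self, genome, rng):
        m = make_molecule(genome, 4, rng, unit_count=2)
        assert m.unit_strands == ("+", "-")

    def test_itr_array_has_no_body_sequence(self, genome, rng):
        """A 5-copy ITR array is ~5*(125+20) nt and contains none of the
        rep-probe region."""
        m = make_molecule(genome, 6, rng, unit_count=5)
        assert len(m.sequence) == 5 * 145
        p0, p1 = genome.feature("rep-probe").start, genome.feature("rep-probe").end
        assert genome.sequence[p0:p1] not in m.sequence

    def test_concatemer_length_conservation(self, genome, rng):
        """Concatemer length = unit lengths plus TRT junction insertions
        minus the ITR pair each TRT replaces (exact arithmetic)."""
        n = 4
        m = make_molecule(genome, 3, rng, unit_count=n)
        unit_len, itr_len = genome.total_len, genome.spec.itr_len
        trt_len = 125 + 2 * 20
        expected = n * unit_len - (n - 1) * 2 * itr_len + (n - 1) * trt_len
        assert len(m.sequence) == expected

    def test_duplex_length_is_twice_unit(self, genome, rng):
        m = make_molecule(genome, 2, rng)
        assert len(m.sequence) == 2 * genome.total_len

    def test_mixed_has_both_junctions(self, genome, rng):
        m = make_molecule(genome, 5, rng, unit_count=4)
        assert "TRT" in m.junction_types
        assert "fold-back" in m.junction_types

    def test_concatemer_needs_two_units(self, genome, rng):
        with pytest.raises(ValueError):
            make_molecule(genome, 3, rng, unit_count=1)

    def test_invalid_category(self, genome, rng):
        with pytest.raises(ValueError):
            make_molecule(genome, 8, rng)


class TestCircularRca:
    def test_single_traversal_of_ht_circle(self, genome, rng):
        """One RCA round of a circular HT dimer is one pass around the
        circle: length = 2 * (body + TRT)."""
        m = make_circular_and_rca(genome, 2, "HT", 1, rng)
        body = genome.total_len - 2 * genome.spec.itr_len
        assert len(m.sequence) == 2 * (body + 165)

    def test_rounds_multiply_length(self, genome, rng):
        m1 = make_circular_and_rca(genome, 1, "HT", 1, np.random.default_rng(5))
        m4 = make_circular_and_rca(genome, 1, "HT", 4, np.random.default_rng(5))
        assert len(m4.sequence) == 4 * len(m1.sequence)

    def test_cut_product_internal_fragments_equal_circle_length(self, genome, rng):
        """After cutting an RCA product of a circular monomer at the enzyme
        site, successive cut positions are one circle length apart."""
        m = make_circular_and_rca(genome, 1, "HT", 4, rng, enzyme="HindIII")
        circle_len = genome.total_len - 2 * genome.spec.itr_len + 165
        cuts = [0, *m.cut_positions, len(m.sequence)]
        gaps = np.diff(cuts)
        assert all(g == circle_len for g in gaps)

    def test_alternating_odd_units_rejected(self, genome, rng):
        with pytest.raises(ValueError, match="even"):
            make_circular_and_rca(genome, 3, "alternating", 2, rng)


class TestErrorModel:
    def test_zero_rates_identity(self, genome, rng):
        seq = genome.sequence
        assert mutate_sequence(seq, 0, 0, 0, rng) == seq

    def test_substitution_rate_matches_binomial_expectation(self, genome):
        """At 5% substitutions over ~10 kb the observed mismatch fraction
        lies within 3 binomial standard deviations of the rate."""
        rng = np.random.default_rng(123)
        seq = genome.sequence + genome.sequence  # ~9.4 kb
        mutated = mutate_sequence(seq, 0.05, 0.0, 0.0, rng)
        frac = mismatch_fraction(seq, mutated)
        se = np.sqrt(0.05 * 0.95 / len(seq))
        assert abs(frac - 0.05) < 3 * se

    def test_reads_reproducible_per_seed(self, genome, tmp_path):
        cfg = SimConfig(category_counts={1: 3, 3: 2}, sub_rate=0.05,
                        ins_rate=0.01, del_rate=0.01, mito_decoy_count=5,
                        seed=42)
        out = []
        for run in range(2):
            mols = simulate_molecules(genome, cfg)
            reads = simulate_reads(mols, cfg)
            path = tmp_path / f"run{run}.fastq"
            write_reads_fastq(reads, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_truth_table_rows_match_reads(self, genome):
        cfg = SimConfig(category_counts={1: 2, 6: 2}, mito_decoy_count=3, seed=9)
        reads = simulate_reads(simulate_molecules(genome, cfg), cfg)
        tt = truth_table(reads)
        assert len(tt) == len(reads)
        assert tt.is_decoy.sum() == 3

    def test_empty_molecule_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_reads([], SimConfig(category_counts={}, seed=1))
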