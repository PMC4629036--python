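import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from record_asm.contig_mapping import (
    ambiguous_fraction,
    map_contigs,
    multiply_covered_positions,
    qmap,
)
from record_asm.pseudoreads import reverse_complement
from record_asm.synthetic_data import random_genome
from conftest import contigs_from, mapping


def edit_distance_dp(a: str, b: str) -> int:
    """Plain O(nm) Levenshtein distance (independent alignment oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestQmap:
    def test_arithmetic(self):
        assert qmap(mapping(ref_end=500, contig_end=500, idy=98.0)) == 49000.0

    def test_longer_mapping_outranks_slightly_more_identical_one(self):
        long = mapping(ref_end=500, contig_end=500, idy=98.0)
        short = mapping(ref_end=400, contig_end=400, idy=99.5)
        assert qmap(long) == 49000.0 and qmap(short) == 39800.0
        assert qmap(long) > qmap(short)

    def test_zero_identity_scores_zero(self):
        assert qmap(mapping(idy=0.0)) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        l1=st.integers(1, 10_000),
        dl=st.integers(1, 1000),
        idy=st.floats(0.1, 99.0),
        didy=st.floats(0.1, 1.0),
    )
    def test_monotone_in_length_and_identity(self, l1, dl, idy, didy):
        base = mapping(ref_end=l1, contig_end=l1, idy=idy)
        longer = mapping(ref_end=l1 + dl, contig_end=l1 + dl, idy=idy)
        better = mapping(ref_end=l1, contig_end=l1, idy=idy + didy)
        assert qmap(longer) > qmap(base)
        assert qmap(better) > qmap(base)


class TestMapContigs:
    def test_exact_substring(self, small_genome):
        contigs = contigs_from(small_genome, [("chr1", 100, 600)])
        (m,) = map_contigs(contigs, small_genome)
        assert (m.ref_start, m.ref_end) == (100, 600)
        assert m.idy_ref == 100.0 and m.L == 500 and m.strand == "+"
        assert (m.contig_start, m.contig_end) == (0, 500)

    def test_reverse_complement_maps_minus_strand(self, small_genome):
        from record_asm._model import Contig, ContigSet

        contigs = ContigSet([Contig("rc", reverse_complement(small_genome["chr1"][:300]))])
        (m,) = map_contigs(contigs, small_genome)
        assert m.strand == "-"
        assert (m.ref_start, m.ref_end) == (0, 300)
        assert m.idy_ref == 100.0

    def test_unrelated_contig_does_not_map(self, small_genome):
        unrelated = random_genome([500], seed=999, names=["x"])
        contigs = contigs_from(unrelated, [("x", 0, 500)])
        assert map_contigs(contigs, small_genome) == []

    def test_full_coverage_identity_for_reference_derived_contigs(self, small_genome):
        contigs = contigs_from(
            small_genome, [("chr1", 0, 2500), ("chr1", 2500, 6000), ("chr1", 6000, 10_000)]
        )
        mappings = map_contigs(contigs, small_genome)
        assert len(mappings) == 3
        for m in mappings:
            assert m.idy_ref == 100.0
            assert (m.contig_start, m.contig_end) == (0, m.L)

    def test_identity_matches_independent_edit_distance(self, small_genome):
        # plant exactly 4 substitutions in a 400 bp segment: identity must be
        # 100 * (400 - 4)/400 and the DP oracle must agree on the distance
        seg = list(small_genome["chr1"][1000:1400])
        for pos in (50, 150, 250, 350):
            seg[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seg[pos]]
        contig_seq = "".join(seg)
        from record_asm._model import Contig, ContigSet

        (m,) = map_contigs(ContigSet([Contig("mut", contig_seq)]), small_genome)
        ref_segment = small_genome["chr1"][m.ref_start : m.ref_end]
        assert edit_distance_dp(contig_seq, ref_segment) == 4
        assert m.idy_ref == pytest.approx(100 * 396 / 400, abs=0.01)

    def test_indel_identity_against_dp_oracle(self, small_genome):
        # delete 3 bases: alignment has 3 gap columns over 400 columns
        seg = small_genome["chr1"][2000:2400]
        contig_seq = seg[:200] + seg[203:]
        from record_asm._model import Contig, ContigSet

        (m,) = map_contigs(ContigSet([Contig("del", contig_seq)]), small_genome)
        ref_segment = small_genome["chr1"][m.ref_start : m.ref_end]
        ed = edit_distance_dp(contig_seq, ref_segment)
        assert ed == 3
        implied_non_match = round((100.0 - m.idy_ref) / 100.0 * 400)
        assert implied_non_match == ed


class TestAmbiguity:
    def test_unique_mappings_are_unambiguous(self):
        ms = [mapping(contig_id=f"c{i}") for i in range(3)]
        assert ambiguous_fraction(ms) == 0.0

    def test_one_of_three_contigs_ambiguous(self):
        ms = [mapping(contig_id="a"), mapping(contig_id="b"), mapping(contig_id="c")]
        ms.append(mapping(contig_id="a", ref_start=500, ref_end=600, contig_end=100))
        assert ambiguous_fraction(ms) == pytest.approx(1 / 3)

    def test_no_mappings_gives_zero(self):
        assert ambiguous_fraction([]) == 0.0

    def test_duplicated_block_produces_ambiguity(self, repeat_genome, repeat_block_span):
        (s1, e1), _ = repeat_block_span
        contigs = contigs_from(repeat_genome, [("chr1", s1, e1), ("chr1", 0, 2000)])
        mappings = map_contigs(contigs, repeat_genome)
        assert ambiguous_fraction(mappings) > 0

    def test_multiply_covered_positions_counts_depth_two_plus(self, small_genome):
        ms = [
            mapping(contig_id="a", ref_start=0, ref_end=100, contig_end=100),
            mapping(contig_id="b", ref_start=50, ref_end=150, contig_end=100),
            mapping(contig_id="c", ref_start=140, ref_end=200, contig_end=60),
        ]
        assert multiply_covered_positions(ms, small_genome) == 60
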