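import pytest

from record_asm._model import Contig, ContigSet, Genome
from record_asm.contig_mapping import map_contigs, multiply_covered_positions
from record_asm.reference_editing import (
    Placement,
    resolve_overlaps,
    select_best_mappings,
    splice_reference,
)
from conftest import contigs_from, mapping


class TestSelectBestMappings:
    def test_highest_qmap_wins(self):
        long = mapping(contig_id="c", ref_end=500, contig_end=500, idy=98.0)
        short = mapping(
            contig_id="c", ref_start=600, ref_end=1000, contig_end=400, idy=99.5
        )
        assert select_best_mappings([short, long]) == [long]

    def test_single_mapping_kept(self):
        m = mapping(contig_id="solo")
        assert select_best_mappings([m]) == [m]

    def test_tie_breaks_to_smaller_coordinate(self):
        a = mapping(contig_id="c", ref_start=500, ref_end=600, contig_end=100, idy=95.0)
        b = mapping(contig_id="c", ref_start=100, ref_end=200, contig_end=100, idy=95.0)
        assert select_best_mappings([a, b]) == [b]

    def test_unmapped_contigs_absent(self):
        ms = [mapping(contig_id="a"), mapping(contig_id="b", ref_start=200, ref_end=300)]
        kept = select_best_mappings(ms)
        assert sorted(m.contig_id for m in kept) == ["a", "b"]


class TestResolveOverlaps:
    def test_simple_overlap_trims_upstream_tail(self):
        a = mapping(contig_id="A", ref_start=0, ref_end=10, contig_end=10)
        b = mapping(contig_id="B", ref_start=5, ref_end=15, contig_end=10)
        placements = resolve_overlaps([a, b])
        ivs = {(p.contig_id, p.ref_start, p.ref_end) for p in placements}
        assert ivs == {("A", 0, 5), ("B", 5, 15)}

    def test_nested_overlap_splits_outer_placement(self):
        a = mapping(contig_id="A", ref_start=0, ref_end=20, contig_end=20)
        b = mapping(contig_id="B", ref_start=5, ref_end=10, contig_end=5)
        placements = resolve_overlaps([a, b])
        ivs = sorted((p.ref_start, p.ref_end, p.contig_id) for p in placements)
        assert ivs == [(0, 5, "A"), (5, 10, "B"), (10, 20, "A")]
        # the outer contig contributes both flanks with matching contig bases
        flanks = [p for p in placements if p.contig_id == "A"]
        assert [(p.contig_start, p.contig_end) for p in flanks] == [(0, 5), (10, 20)]

    def test_disjoint_placements_unchanged(self):
        a = mapping(contig_id="A", ref_start=0, ref_end=10, contig_end=10)
        b = mapping(contig_id="B", ref_start=20, ref_end=30, contig_end=10)
        placements = resolve_overlaps([a, b])
        assert {(p.contig_id, p.ref_start, p.ref_end) for p in placements} == {
            ("A", 0, 10),
            ("B", 20, 30),
        }

    def test_three_way_overlap_single_sweep(self):
        a = mapping(contig_id="A", ref_start=0, ref_end=30, contig_end=30)
        b = mapping(contig_id="B", ref_start=5, ref_end=12, contig_end=7)
        c = mapping(contig_id="C", ref_start=8, ref_end=20, contig_end=12)
        placements = resolve_overlaps([a, b, c])
        ivs = sorted((p.ref_start, p.ref_end, p.contig_id) for p in placements)
        assert ivs == [(0, 5, "A"), (5, 8, "B"), (8, 20, "C"), (20, 30, "A")]
        # pairwise disjoint
        spans = sorted((p.ref_start, p.ref_end) for p in placements)
        assert all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))

    def test_fully_shadowed_placement_dropped(self):
        a = mapping(contig_id="A", ref_start=5, ref_end=10, contig_end=5)
        b = mapping(contig_id="B", ref_start=5, ref_end=15, contig_end=10)
        placements = resolve_overlaps([a, b])
        assert {p.contig_id for p in placements} == {"B"}


class TestSpliceReference:
    def test_hand_splice(self):
        ref = Genome({"c": "AAAAATTTTT"})
        contigs = ContigSet([Contig("x", "CCCC")])
        m = mapping(contig_id="x", ref_chrom="c", ref_start=2, ref_end=6, contig_end=4)
        placements = resolve_overlaps([m])
        edited, report = splice_reference(ref, placements, contigs, compute_identity=False)
        assert edited["c"] == "AACCCCTTTT"
        assert report.replaced_length == 4 and report.n_contigs_used == 1

    def test_zero_placements_is_identity(self):
        ref = Genome({"c": "AAAAATTTTT"})
        edited, report = splice_reference(ref, [], ContigSet([]), compute_identity=False)
        assert edited.sequences == ref.sequences
        assert (report.pct_ref, report.pct_asm, report.n_contigs_used) == (0.0, 0.0, 0)

    def test_length_changes_through_indel(self):
        ref = Genome({"c": "AAAAATTTTT"})
        contigs = ContigSet([Contig("x", "CCCCC")])
        m = mapping(contig_id="x", ref_chrom="c", ref_start=2, ref_end=6, contig_end=5)
        edited, report = splice_reference(
            ref, resolve_overlaps([m]), contigs, compute_identity=False
        )
        assert edited["c"] == "AACCCCCTTTT"
        assert report.edited_length == 11

    def test_minus_strand_segment_reverse_complemented(self):
        ref = Genome({"c": "AAAAATTTTT"})
        contigs = ContigSet([Contig("x", "GGGG")])
        m = mapping(
            contig_id="x", ref_chrom="c", ref_start=2, ref_end=6, contig_end=4, strand="-"
        )
        edited, _ = splice_reference(
            ref, resolve_overlaps([m]), contigs, compute_identity=False
        )
        assert edited["c"] == "AACCCCTTTT"

    def test_conservation_identity(self):
        ref = Genome({"c": "A" * 50 + "T" * 50})
        contigs = ContigSet([Contig("x", "CCCCCCC"), Contig("y", "GGG")])
        ms = [
            mapping(contig_id="x", ref_chrom="c", ref_start=10, ref_end=20, contig_end=7),
            mapping(contig_id="y", ref_chrom="c", ref_start=60, ref_end=62, contig_end=3),
        ]
        edited, report = splice_reference(
            ref, resolve_overlaps(ms), contigs, compute_identity=False
        )
        used = sum(p.contig_end - p.contig_start for p in resolve_overlaps(ms))
        assert report.edited_length == ref.total_length - report.replaced_length + used
        assert report.edited_length == len(edited["c"])

    def test_overlapping_placements_rejected(self):
        ref = Genome({"c": "AAAAATTTTT"})
        contigs = ContigSet([Contig("x", "CCCC"), Contig("y", "GGGG")])
        raw = [
            Placement(mapping(contig_id="x", ref_chrom="c", ref_start=0, ref_end=4, contig_end=4), 0, 4, 0, 4),
            Placement(mapping(contig_id="y", ref_chrom="c", ref_start=2, ref_end=6, contig_end=4), 2, 6, 0, 4),
        ]
        with pytest.raises(ValueError, match="overlap"):
            splice_reference(ref, raw, contigs, compute_identity=False)


class TestSelectionReducesMultipleCoverage:
    def test_multiply_covered_positions_strictly_decrease(
        self, repeat_genome, repeat_block_span
    ):
        (s1, e1), (s2, e2) = repeat_block_span
        contigs = contigs_from(
            repeat_genome,
            [("chr1", s1 - 200, e1 + 200), ("chr1", s2 - 200, e2 + 200), ("chr1", 0, 2000)],
        )
        raw = map_contigs(contigs, repeat_genome)
        before = multiply_covered_positions(raw, repeat_genome)
        after = multiply_covered_positions(select_best_mappings(raw), repeat_genome)
        assert before > 0
        assert after < before


class TestEditedReferenceApproachesTarget:
    def test_splicing_target_segments_increases_target_identity(self, small_genome):
        from record_asm.evaluation import idy_and_error
        from record_asm.synthetic_data import EvolutionParams, evolve

        target, _ = evolve(small_genome, EvolutionParams(snp_rate=0.01, ins_rate=0, del_rate=0, seed=3))
        contigs = ContigSet(
            [Contig(f"t{i}", target["chr1"][s:e]) for i, (s, e) in enumerate([(0, 4000), (4500, 9000)])]
        )
        mappings = map_contigs(contigs, small_genome)
        placements = resolve_overlaps(select_best_mappings(mappings))
        edited, _ = splice_reference(small_genome, placements, contigs, compute_identity=False)
        idy_edit, _ = idy_and_error(edited, target)
        idy_ref, _ = idy_and_error(small_genome, target)
        assert idy_edit > idy_ref
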