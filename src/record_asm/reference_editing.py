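"""Best-mapping selection, greedy overlap resolution, and reference splicing.

After mapping, each contig keeps only its highest-Q_map placement. Residual
overlaps between the reference intervals of different contigs are resolved
greedily in favour of contig *beginnings*: wherever two placements overlap,
the one starting further right keeps its start and the earlier one is
trimmed back. A placement fully straddling a nested one contributes both of
its flanks, so a contig may end up with several effective segments. Finally
the edited reference is produced by replacing each placed reference
interval with the corresponding contig segment (reverse-complemented first
for minus-strand placements), leaving everything else untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

from ._model import ContigSet, Genome, MappingRecord, reverse_complement
from .contig_mapping import qmap

__all__ = [
    "Placement",
    "EditReport",
    "select_best_mappings",
    "resolve_overlaps",
    "splice_reference",
]


@dataclass
class Placement:
    """An effective (possibly trimmed) segment of a selected mapping.

    ``ref_start/ref_end`` is the reference interval actually replaced and
    ``contig_start/contig_end`` the contig bases spliced in. After
    :func:`resolve_overlaps`, reference intervals are pairwise disjoint per
    chromosome; one contig may own several placements when a nested overlap
    split it.
    """

    mapping: MappingRecord
    ref_start: int
    ref_end: int
    contig_start: int
    contig_end: int

    @property
    def ref_chrom(self) -> str:
        return self.mapping.ref_chrom

    @property
    def contig_id(self) -> str:
        return self.mapping.contig_id

    @property
    def strand(self) -> str:
        return self.mapping.strand


@dataclass
class EditReport:
    """Summary statistics of one reference-editing run."""

    edited_length: int
    replaced_length: int
    pct_ref: float
    pct_asm: float
    n_contigs_used: int
    pct_idy_vs_ref: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def select_best_mappings(mappings: Sequence[MappingRecord]) -> list[MappingRecord]:
    """Keep, for each contig, the single mapping with the highest Q_map.

    Ties break deterministically toward the smaller (chromosome, ref_start,
    '+' strand). Contigs with no mapping are simply absent.
    """
    best: dict[str, MappingRecord] = {}
    for m in mappings:
        cur = best.get(m.contig_id)
        if cur is None or _selection_key(m) > _selection_key(cur):
            best[m.contig_id] = m
    return sorted(best.values(), key=lambda m: (m.ref_chrom, m.ref_start, m.contig_id))


def _selection_key(m: MappingRecord):
    # maximize qmap; on ties prefer smaller (chrom, ref_start) and '+' strand
    return (qmap(m), _Rev(m.ref_chrom), -m.ref_start, m.strand == "+")


class _Rev:
    """Reverses comparison order so max() prefers the smaller string."""

    __slots__ = ("v",)

    def __init__(self, v):
        self.v = v

    def __eq__(self, other):
        return self.v == other.v

    def __lt__(self, other):
        return self.v > other.v

    def __gt__(self, other):
        return self.v < other.v


def resolve_overlaps(selected: Sequence[MappingRecord]) -> list[Placement]:
    """Resolve residual overlaps among per-contig best mappings.

    Every reference position is assigned to the covering mapping with the
    largest ``ref_start`` — the later-starting contig keeps its beginning
    and the earlier one is trimmed (or split, when the overlap is nested).
    Trimming removes reference columns; the matching contig bases are found
    by integer proportional scaling of the mapping's contig interval.
    Placements whose effective interval becomes empty are dropped.
    """
    by_chrom: dict[str, list[MappingRecord]] = {}
    for m in selected:
        by_chrom.setdefault(m.ref_chrom, []).append(m)

    placements: list[Placement] = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: (m.ref_start, m.ref_end, m.contig_id))
        bounds = sorted({b for m in ms for b in (m.ref_start, m.ref_end)})
        # owner of each elementary interval: covering mapping with max ref_start
        segments: list[tuple[MappingRecord, int, int]] = []
        for lo, hi in zip(bounds, bounds[1:]):
            covering = [m for m in ms if m.ref_start <= lo and m.ref_end >= hi]
            if not covering:
                continue
            owner = max(
                covering, key=lambda m: (m.ref_start, m.ref_end, m.contig_id)
            )
            if segments and segments[-1][0] is owner and segments[-1][2] == lo:
                prev = segments.pop()
                segments.append((owner, prev[1], hi))
            else:
                segments.append((owner, lo, hi))
        for owner, lo, hi in segments:
            cs, ce = _contig_subinterval(owner, lo, hi)
            if ce > cs:
                placements.append(Placement(owner, lo, hi, cs, ce))
    return placements


def _contig_subinterval(m: MappingRecord, lo: int, hi: int) -> tuple[int, int]:
    """Contig bases corresponding to reference columns [lo, hi) of mapping m,
    by integer proportional scaling (floor, i.e. rounding toward fewer
    contig bases)."""
    rlen = m.ref_end - m.ref_start
    clen = m.contig_end - m.contig_start

    def fwd(x: int) -> int:
        return m.contig_start + (x - m.ref_start) * clen // rlen

    def rev(x: int) -> int:
        return m.contig_end - (x - m.ref_start) * clen // rlen

    if m.strand == "+":
        return fwd(lo), fwd(hi)
    return rev(hi), rev(lo)


def splice_reference(
    reference: Genome,
    placements: Sequence[Placement],
    contigs: ContigSet,
    compute_identity: bool = True,
) -> tuple[Genome, EditReport]:
    """Replace placed reference intervals with contig segments.

    Returns the edited reference and an :class:`EditReport`. Minus-strand
    contig segments are reverse-complemented so the output stays in
    reference orientation. Edited chromosome lengths may differ from the
    original where contig and reference segment lengths differ (indels).
    With ``compute_identity`` the report includes the percent identity of
    the edited reference against the original.
    """
    by_chrom: dict[str, list[Placement]] = {}
    for p in placements:
        by_chrom.setdefault(p.ref_chrom, []).append(p)

    edited: dict[str, str] = {}
    replaced = used_bases = 0
    used_contigs: set[str] = set()
    for chrom, seq in reference.items():
        ps = sorted(by_chrom.get(chrom, []), key=lambda p: p.ref_start)
        parts: list[str] = []
        cursor = 0
        for p in ps:
            if p.ref_start < cursor:
                raise ValueError(
                    f"overlapping placements on {chrom} at {p.ref_start} "
                    f"(previous placement ends at {cursor})"
                )
            parts.append(seq[cursor : p.ref_start])
            segment = contigs.get(p.contig_id).seq[p.contig_start : p.contig_end]
            if p.strand == "-":
                segment = reverse_complement(segment)
            parts.append(segment)
            cursor = p.ref_end
            replaced += p.ref_end - p.ref_start
            used_bases += p.contig_end - p.contig_start
            used_contigs.add(p.contig_id)
        parts.append(seq[cursor:])
        edited[chrom] = "".join(parts)

    edited_genome = Genome(edited)
    total_contig_bases = contigs.total_length
    report = EditReport(
        edited_length=edited_genome.total_length,
        replaced_length=replaced,
        pct_ref=100.0 * replaced / reference.total_length,
        pct_asm=(100.0 * used_bases / total_contig_bases) if total_contig_bases else 0.0,
        n_contigs_used=len(used_contigs),
    )
    if compute_identity:
        from .evaluation import idy_and_error

        idy, _err = idy_and_error(edited_genome, reference)
        report.pct_idy_vs_ref = idy
    return edited_genome, report
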