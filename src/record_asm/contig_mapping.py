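"""Seed-and-extend mapping of contigs to a reference, and Q_map scoring.

Mapping quality is scored as ``Q_map = L x idy_ref`` — an estimate of the
number of identical bases between a contig segment and the reference
segment it maps to. Longer and more identical mappings are both more likely
to be placed correctly, and Q_map ranks exactly that.

The mapper finds exact k-mer seed matches against both reference strands,
clusters colinear seeds per (chromosome, strand, diagonal band), and
resolves each cluster with a banded edit-distance alignment (edlib).
Percent identity is matches over alignment columns (gaps count as columns),
reported to 2 decimals. A contig may yield zero, one or many mapping
records; ambiguity is quantified by :func:`ambiguous_fraction`.
"""

from __future__ import annotations

from typing import Sequence

import edlib
import numpy as np

from . import _kmers
from ._model import ContigSet, Genome, MappingRecord, reverse_complement

__all__ = [
    "qmap",
    "map_contigs",
    "ambiguous_fraction",
    "multiply_covered_positions",
    "ReferenceIndex",
    "MIN_MATCH_LEN",
    "MIN_IDY",
]

#: default minimum mapped-segment length (a MUMmer-like useful-alignment floor)
MIN_MATCH_LEN = 65
#: default minimum percent identity — the genomes are assumed very closely related
MIN_IDY = 90.0

_INDEX_K = 21
_MAX_HITS_PER_KMER = 100
_MAX_CLUSTERS_PER_CONTIG = 25
_MIN_SEEDS_PER_CLUSTER = 2


def qmap(mapping: MappingRecord) -> float:
    """Q_map score of a mapping: ``L x idy_ref`` (base-percent units)."""
    return mapping.L * mapping.idy_ref


class ReferenceIndex:
    """Sorted-array k-mer index over the forward strand of a genome."""

    def __init__(self, reference: Genome, k: int = _INDEX_K) -> None:
        self.k = k
        self.chrom_names = reference.names
        self.chrom_lengths = [len(reference[c]) for c in self.chrom_names]
        # concatenate chromosomes with an N spacer so no window spans two
        concat = "N".join(reference[c] for c in self.chrom_names)
        self.offsets = np.zeros(len(self.chrom_names), dtype=np.int64)
        off = 0
        for i, length in enumerate(self.chrom_lengths):
            self.offsets[i] = off
            off += length + 1
        codes = _kmers.encode(concat)
        fwd, _rc, valid = _kmers.kmer_windows(codes, k)
        positions = np.nonzero(valid)[0]
        kmers = fwd[valid]
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.positions = positions[order]

    def lookup(self, query_kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Hits of ``query_kmers``: (query indices, global reference positions)."""
        left = np.searchsorted(self.sorted_kmers, query_kmers, "left")
        right = np.searchsorted(self.sorted_kmers, query_kmers, "right")
        counts = np.minimum(right - left, _MAX_HITS_PER_KMER)
        total = int(counts.sum())
        if total == 0:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        qidx = np.repeat(np.arange(query_kmers.size), counts)
        starts = np.repeat(left, counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        return qidx, self.positions[starts + within]

    def chrom_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, "right") - 1


def map_contigs(
    contigs: ContigSet,
    reference: Genome,
    min_match_len: int = MIN_MATCH_LEN,
    min_idy: float = MIN_IDY,
    index: ReferenceIndex | None = None,
) -> list[MappingRecord]:
    """Map every contig to the reference; returns all passing alignments.

    Records shorter than ``min_match_len`` or below ``min_idy`` percent
    identity are suppressed. The same contig may map to several reference
    segments (e.g. repeats), producing several records.
    """
    if not contigs:
        return []
    if index is None:
        index = ReferenceIndex(reference)
    k = index.k
    records: list[MappingRecord] = []
    for contig in contigs:
        if len(contig.seq) < k:
            continue
        codes = _kmers.encode(contig.seq)
        fwd, rc, valid = _kmers.kmer_windows(codes, k)
        for strand, query in (("+", fwd), ("-", rc)):
            qkm = np.where(valid, query, np.uint64(0))
            qidx, rpos = index.lookup(qkm)
            if qidx.size:
                keep = valid[qidx]
                qidx, rpos = qidx[keep], rpos[keep]
            if qidx.size < _MIN_SEEDS_PER_CLUSTER:
                continue
            records.extend(
                _cluster_and_align(
                    contig, strand, qidx, rpos, index, reference, min_match_len, min_idy
                )
            )
    # deduplicate identical placements (clusters can converge after alignment)
    seen: set[tuple] = set()
    out: list[MappingRecord] = []
    for r in records:
        key = (r.contig_id, r.ref_chrom, r.ref_start, r.ref_end, r.strand)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def _cluster_and_align(
    contig,
    strand: str,
    qidx: np.ndarray,
    rpos: np.ndarray,
    index: ReferenceIndex,
    reference: Genome,
    min_match_len: int,
    min_idy: float,
) -> list[MappingRecord]:
    k = index.k
    clen = len(contig.seq)
    band = max(20, clen // 10)
    # minus-strand hits: seed at contig window q matches reference in reverse
    # orientation; use the coordinate of the *reverse-complemented* contig so
    # that diagonals are additive again
    q_eff = qidx if strand == "+" else (clen - k) - qidx
    diag = rpos - q_eff
    chrom_idx = index.chrom_of(rpos)
    order = np.lexsort((q_eff, diag, chrom_idx))
    q_s, r_s, d_s, c_s = q_eff[order], rpos[order], diag[order], chrom_idx[order]

    # cluster colinear hits: same chromosome, diagonal within the band
    # (1% divergence implies small indel drift, well under the band)
    breaks = np.nonzero((np.diff(c_s) != 0) | (np.abs(np.diff(d_s)) > band))[0]
    bounds = np.concatenate(([0], breaks + 1, [q_s.size]))
    clusters = []
    for i in range(bounds.size - 1):
        lo, hi = bounds[i], bounds[i + 1]
        if hi - lo < _MIN_SEEDS_PER_CLUSTER:
            continue
        span = int(q_s[lo:hi].max() - q_s[lo:hi].min()) + k
        if span < min_match_len:
            continue
        # genuine near-identical matches have dense seed support; sparse
        # wide clusters are random collisions not worth aligning
        if (hi - lo) / max(1, span - k + 1) < 0.05:
            continue
        clusters.append((hi - lo, lo, hi))
    clusters.sort(reverse=True)
    clusters = clusters[:_MAX_CLUSTERS_PER_CONTIG]

    rc_query = None
    out = []
    for _, lo, hi in clusters:
        ci = int(c_s[lo])
        chrom = index.chrom_names[ci]
        off = int(index.offsets[ci])
        if strand == "+":
            query = contig.seq
        else:
            if rc_query is None:
                rc_query = reverse_complement(contig.seq)
            query = rc_query
        result = _chain_and_stitch(
            query, reference[chrom], q_s[lo:hi], r_s[lo:hi] - off, k, band, min_idy
        )
        if result is None:
            continue
        qs, qe, ref_start, ref_end, matches, columns = result
        if columns == 0 or ref_start >= ref_end:
            continue
        idy = round(100.0 * matches / columns, 2)
        seg_len = qe - qs
        if seg_len < min_match_len or idy < min_idy:
            continue
        if strand == "+":
            cstart, cend = qs, qe
        else:
            cstart, cend = clen - qe, clen - qs
        out.append(
            MappingRecord(
                ref_chrom=chrom,
                ref_start=ref_start,
                ref_end=ref_end,
                contig_id=contig.id,
                contig_start=cstart,
                contig_end=cend,
                strand=strand,
                idy_ref=idy,
                L=seg_len,
            )
        )
    return out


_FLANK_CAP = 400  # longest unseeded end extended by alignment


def _chain_and_stitch(
    query: str,
    ref_seq: str,
    q_hits: np.ndarray,
    r_hits: np.ndarray,
    k: int,
    band: int,
    min_idy: float,
) -> tuple[int, int, int, int, int, int] | None:
    """Resolve one seed cluster into alignment statistics.

    Picks a colinear chain of exact k-mer hits, merges consecutive hits into
    maximal exact anchors, aligns the short gaps between anchors with
    global edit-distance alignment, and extends the ends (up to a cap) with
    prefix alignments. An end extension whose own identity falls below
    ``min_idy`` is discarded, so a contig that only partially matches (e.g.
    one copy of a repeat plus unique flanks) maps as a segment instead of
    being dragged below the identity threshold. Returns ``(q_start, q_end,
    ref_start, ref_end, match_columns, total_columns)`` or None for a
    degenerate cluster.
    """
    order = np.argsort(q_hits, kind="stable")
    qh = q_hits[order].tolist()
    rh = r_hits[order].tolist()
    d0 = float(np.median(r_hits - q_hits))

    # greedy colinear chain: strictly increasing q and r, diagonal in band
    chain_q: list[int] = []
    chain_r: list[int] = []
    prev_q = prev_r = -1
    for q, r in zip(qh, rh):
        if q <= prev_q or r <= prev_r or abs((r - q) - d0) > band:
            continue
        chain_q.append(q)
        chain_r.append(r)
        prev_q, prev_r = q, r
    if not chain_q:
        return None

    # merge runs of consecutive windows into exact anchors [qa, qe), [ra, re)
    anchors: list[list[int]] = []
    for q, r in zip(chain_q, chain_r):
        if anchors and q == anchors[-1][1] - k + 1 and r == anchors[-1][3] - k + 1:
            anchors[-1][1] += 1
            anchors[-1][3] += 1
        else:
            anchors.append([q, q + k, r, r + k])

    matches = columns = 0
    aq, ae, ar, re_ = anchors[0]
    merged: list[tuple[int, int, int, int]] = [(aq, ae, ar, re_)]
    for qa, qe, ra, re_ in anchors[1:]:
        pq, pe, pr, pre = merged[-1]
        # clip overlap with the previous anchor (repeat slippage)
        o = max(pe - qa, pre - ra, 0)
        qa, ra = qa + o, ra + o
        if qa >= qe or ra >= re_:
            continue
        merged.append((qa, qe, ra, re_))

    for i, (qa, qe, ra, re_) in enumerate(merged):
        matches += qe - qa
        columns += qe - qa
        if i == 0:
            continue
        _pq, pe, _pr, pre = merged[i - 1]
        gq = query[pe:qa]
        gr = ref_seq[pre:ra]
        if gq and gr:
            aln = edlib.align(gq, gr, mode="NW", task="path")
            m, c = _cigar_stats(aln["cigar"])
            matches += m
            columns += c
        else:
            columns += max(len(gq), len(gr))  # pure insertion/deletion

    q_start, q_end = merged[0][0], merged[-1][1]
    ref_start, ref_end = merged[0][2], merged[-1][3]

    # left flank: align the unseeded query prefix outward from the first anchor
    lflank = query[max(0, q_start - _FLANK_CAP) : q_start]
    if lflank:
        target = ref_seq[max(0, ref_start - len(lflank) - band) : ref_start]
        if target:
            aln = edlib.align(lflank[::-1], target[::-1], mode="SHW", task="path")
            m, c = _cigar_stats(aln["cigar"])
            if c and 100.0 * m / c >= min_idy:
                matches += m
                columns += c
                ref_start -= aln["locations"][0][1] + 1
                q_start -= len(lflank)

    # right flank, symmetric
    rflank = query[q_end : q_end + _FLANK_CAP]
    if rflank:
        target = ref_seq[ref_end : ref_end + len(rflank) + band]
        if target:
            aln = edlib.align(rflank, target, mode="SHW", task="path")
            m, c = _cigar_stats(aln["cigar"])
            if c and 100.0 * m / c >= min_idy:
                matches += m
                columns += c
                ref_end += aln["locations"][0][1] + 1
                q_end += len(rflank)

    return q_start, q_end, ref_start, ref_end, matches, columns


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(match columns, total alignment columns) from an extended cigar."""
    matches = columns = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            columns += num
            if ch == "=":
                matches += num
            num = 0
    return matches, columns


def ambiguous_fraction(
    mappings: Sequence[MappingRecord], contigs: ContigSet | None = None
) -> float:
    """Proportion of mapped contigs that map to 2+ reference segments.

    Defined as (# contigs with >=2 mappings) / (# contigs with >=1 mapping);
    0.0 when nothing maps.
    """
    counts: dict[str, int] = {}
    for m in mappings:
        counts[m.contig_id] = counts.get(m.contig_id, 0) + 1
    if not counts:
        return 0.0
    multi = sum(1 for n in counts.values() if n >= 2)
    return multi / len(counts)


def multiply_covered_positions(
    mappings: Sequence[MappingRecord], reference: Genome
) -> int:
    """Number of reference positions covered by 2+ mapped contig segments."""
    total = 0
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in mappings:
        per_chrom.setdefault(m.ref_chrom, []).append((m.ref_start, m.ref_end))
    for chrom, ivs in per_chrom.items():
        cov = np.zeros(len(reference[chrom]) + 1, dtype=np.int32)
        for s, e in ivs:
            cov[s] += 1
            cov[e] -= 1
        depth = np.cumsum(cov[:-1])
        total += int((depth >= 2).sum())
    return total
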