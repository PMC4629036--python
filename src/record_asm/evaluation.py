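"""Assembly-quality metrics: TL, N50, weighted identity/error, coverage.

Identity between an assembly (contigs or a whole genome) and the target is
the length-weighted mean of the percent identities of all its mapped
segments, with the mapped-segment lengths as weights; Error is its
complement (100 - IDY). The number of identical bases is estimated as
IDY x TL. Interval statistics (covered target bases, contigs-to-half) are
computed on half-open interval unions, merging adjacent intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from ._model import Contig, ContigSet, Genome, MappingRecord
from .contig_mapping import MIN_IDY, MIN_MATCH_LEN, map_contigs

__all__ = [
    "EvaluationReport",
    "total_length",
    "n50",
    "weighted_identity",
    "idy_and_error",
    "identical_bases",
    "bases_to_mb",
    "coverage",
    "covered_target_bases",
    "n_contigs_to_half_target",
    "evaluate_assembly",
    "NoAlignmentError",
]


class NoAlignmentError(RuntimeError):
    """Nothing in the assembly could be mapped to the target."""


@dataclass
class EvaluationReport:
    TL: int
    TL_mb: float
    N50: int
    IDY: float
    Error: float
    identical_bases: float
    identical_bases_mb: float
    covered_target_bases: int
    n_contigs_to_half_target: int | None
    Cov: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def total_length(contigs: ContigSet) -> int:
    """Total assembly length in bases (0 for an empty set)."""
    return contigs.total_length


def n50(contigs: ContigSet | Sequence[int]) -> int:
    """Shortest contig in the minimal set of largest contigs covering at
    least half of the total assembly length."""
    lengths = contigs.lengths if isinstance(contigs, ContigSet) else list(contigs)
    if not lengths:
        raise ValueError("N50 is undefined for an empty contig set")
    lengths = sorted(lengths, reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def weighted_identity(mappings: Sequence[MappingRecord]) -> float:
    """Length-weighted mean percent identity over mapped segments."""
    total_l = sum(m.L for m in mappings)
    if total_l == 0:
        raise NoAlignmentError("no mapped segments to average over")
    return sum(m.L * m.idy_ref for m in mappings) / total_l


def idy_and_error(
    assembly: ContigSet | Genome,
    target: Genome,
    mappings: Sequence[MappingRecord] | None = None,
    min_match_len: int = MIN_MATCH_LEN,
    min_idy: float = MIN_IDY,
) -> tuple[float, float]:
    """(IDY, Error) of an assembly against a target genome.

    Maps the assembly to the target (unless pre-computed ``mappings``,
    e.g. ingested from a coords file, are given) and averages segment
    identities weighted by mapped length. Raises :class:`NoAlignmentError`
    when nothing maps.
    """
    contigs = _as_contig_set(assembly)
    if mappings is None:
        mappings = map_contigs(contigs, target, min_match_len=min_match_len, min_idy=min_idy)
    if not mappings:
        raise NoAlignmentError("assembly does not align to the target genome")
    idy = weighted_identity(mappings)
    return idy, 100.0 - idy


def _as_contig_set(assembly: ContigSet | Genome) -> ContigSet:
    if isinstance(assembly, Genome):
        return ContigSet([Contig(name, seq) for name, seq in assembly.items()])
    return assembly


def identical_bases(tl_bases: float, idy: float) -> float:
    """Estimated identical bases: TL x IDY / 100."""
    if not 0.0 <= idy <= 100.0:
        raise ValueError("IDY must lie in [0, 100]")
    return tl_bases * idy / 100.0


def bases_to_mb(bases: float) -> float:
    """Bases -> megabases, rounded half-up to 2 decimals (report format)."""
    return float(Decimal(repr(bases / 1e6)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def coverage(read_length: float, n_reads: float, genome_size: float) -> float:
    """Fold coverage: read_length x number_of_reads / genome_size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return read_length * n_reads / genome_size


def _merged_intervals(
    mappings: Sequence[MappingRecord],
) -> dict[str, list[tuple[int, int]]]:
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in mappings:
        per_chrom.setdefault(m.ref_chrom, []).append((m.ref_start, m.ref_end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:  # overlapping or adjacent: merge
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def covered_target_bases(mappings: Sequence[MappingRecord]) -> int:
    """Union length of mapped target intervals (overlaps counted once)."""
    merged = _merged_intervals(mappings)
    return sum(e - s for ivs in merged.values() for s, e in ivs)


def n_contigs_to_half_target(
    contigs: ContigSet,
    mappings: Sequence[MappingRecord],
    target: Genome,
) -> int | None:
    """Minimal number of largest contigs whose mapped target intervals
    together cover at least 50% of the target; None if unreachable."""
    by_contig: dict[str, list[MappingRecord]] = {}
    for m in mappings:
        by_contig.setdefault(m.contig_id, []).append(m)
    half = target.total_length / 2
    acc: list[MappingRecord] = []
    count = 0
    ordered = sorted(contigs, key=lambda c: (-len(c), c.id))
    for contig in ordered:
        count += 1
        acc.extend(by_contig.get(contig.id, []))
        if covered_target_bases(acc) >= half:
            return count
    return None


def evaluate_assembly(
    assembly: ContigSet | Genome,
    target: Genome,
    mappings: Sequence[MappingRecord] | None = None,
    read_length: float | None = None,
    n_reads: float | None = None,
) -> EvaluationReport:
    """Full metric suite for one assembly against a target genome."""
    contigs = _as_contig_set(assembly)
    if mappings is None:
        mappings = map_contigs(contigs, target)
    if not mappings:
        raise NoAlignmentError("assembly does not align to the target genome")
    tl = total_length(contigs)
    idy, err = idy_and_error(contigs, target, mappings=mappings)
    ident = identical_bases(tl, idy)
    cov = None
    if read_length is not None and n_reads is not None:
        cov = coverage(read_length, n_reads, target.total_length)
    return EvaluationReport(
        TL=tl,
        TL_mb=bases_to_mb(tl),
        N50=n50(contigs),
        IDY=idy,
        Error=err,
        identical_bases=ident,
        identical_bases_mb=bases_to_mb(ident),
        covered_target_bases=covered_target_bases(mappings),
        n_contigs_to_half_target=n_contigs_to_half_target(contigs, mappings, target),
        Cov=cov,
    )
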