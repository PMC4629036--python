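"""Synthetic study data: random genomes, simulated evolution, read simulation.

This module provides the in-silico counterpart of a real resequencing
study: a multi-chromosome reference, a "target" genome evolved from it at a
controlled (by default ~1%) divergence through point substitutions and
short geometric indels, and wgsim-style paired-end reads drawn from the
target. Ground truth (every mutation event) is retained so downstream
results can be checked against what was actually simulated. All operations
take explicit seeds; there is no hidden global RNG.

Deliberately not emulated: rearrangements, mobile elements, duplications,
and instrument-specific error/quality profiles — the pipeline targets
point-mutation-scale divergence between very closely related genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from . import _kmers
from ._model import Genome, ReadPair

__all__ = [
    "EvolutionParams",
    "ReadSimParams",
    "TruthEvent",
    "random_genome",
    "evolve",
    "simulate_reads",
    "realized_divergence",
    "write_truth_log",
]


@dataclass
class EvolutionParams:
    """Per-base mutation rates for :func:`evolve`.

    Defaults give ~1% SNP divergence with occasional short indels
    (geometric lengths, mean 3) — the closely-related-genomes regime the
    pipeline is built for.
    """

    snp_rate: float = 0.01
    ins_rate: float = 5e-4
    del_rate: float = 5e-4
    indel_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.snp_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ValueError("total per-base event rate must be < 1")
        if self.indel_mean < 1.0:
            raise ValueError("indel_mean must be >= 1")


@dataclass
class ReadSimParams:
    """Paired-end read simulation parameters (wgsim-style).

    Error-free 70 bp pairs from ~500 bp fragments at constant Q40 by
    default, so simulated experimental bases decisively outvote Q10
    pseudoreads in the assembler.
    """

    n_pairs: int
    read_length: int = 70
    fragment_mean: int = 500
    fragment_sd: float = 50.0
    base_error_rate: float = 0.0
    quality: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if min(self.read_length, self.fragment_mean) <= 0 or self.fragment_sd < 0:
            raise ValueError("read_length/fragment parameters must be positive")
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ValueError("base_error_rate must lie in [0, 1)")
        if not 0 <= self.quality <= 93:
            raise ValueError("quality must lie in the Phred range [0, 93]")


@dataclass
class TruthEvent:
    """One recorded mutation, in reference coordinates."""

    chrom: str
    pos: int
    type: str  # "snp" | "ins" | "del"
    ref_allele: str
    alt_allele: str


def random_genome(
    lengths: Sequence[int],
    gc: float = 0.41,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> Genome:
    """I.i.d. random genome at the given GC fraction; deterministic per seed.

    The default GC of 0.41 is mammalian-like.
    """
    if not lengths or any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"chr{i + 1}" for i in range(len(lengths))]
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences = {}
    for name, length in zip(names, lengths, strict=True):
        codes = rng.choice(4, size=length, p=p).astype(np.uint8)
        sequences[name] = _kmers.decode(codes)
    return Genome(sequences)


def evolve(genome: Genome, params: EvolutionParams) -> tuple[Genome, list[TruthEvent]]:
    """Evolve a target genome by independent per-base events.

    Substitutions go to a uniformly chosen different base; insertions and
    deletions have geometric lengths with mean ``indel_mean``. Every applied
    event is recorded with reference coordinates. Substitutions are applied
    first, then indels left to right (a deletion removes the possibly
    substituted bases; the logged alleles are the original reference ones).
    """
    rng = np.random.default_rng(params.seed)
    target: dict[str, str] = {}
    events: list[TruthEvent] = []
    for chrom, seq in genome.items():
        codes = _kmers.encode(seq)
        n_mask = codes >= 4
        length = codes.size
        u = rng.random(length)
        snp_pos = np.nonzero((u < params.snp_rate) & ~n_mask)[0]
        lo = params.snp_rate
        ins_pos = np.nonzero((u >= lo) & (u < lo + params.ins_rate))[0]
        lo += params.ins_rate
        del_pos = np.nonzero((u >= lo) & (u < lo + params.del_rate))[0]

        mutated = codes.copy()
        if snp_pos.size:
            shifts = rng.integers(1, 4, size=snp_pos.size).astype(np.uint8)
            mutated[snp_pos] = (codes[snp_pos] + shifts) % 4
            for p, old, new in zip(
                snp_pos.tolist(), codes[snp_pos].tolist(), mutated[snp_pos].tolist()
            ):
                events.append(TruthEvent(chrom, p, "snp", "ACGT"[old], "ACGT"[new]))

        geom_p = 1.0 / params.indel_mean
        indels: list[tuple[int, str, int]] = []  # (pos, kind, length)
        for p in ins_pos.tolist():
            indels.append((p, "ins", int(rng.geometric(geom_p))))
        for p in del_pos.tolist():
            indels.append((p, "del", int(rng.geometric(geom_p))))
        indels.sort()

        parts: list[np.ndarray] = []
        cursor = 0
        for pos, kind, ilen in indels:
            if pos < cursor:  # swallowed by a previous deletion
                continue
            if kind == "ins":
                parts.append(mutated[cursor:pos])
                insert = rng.integers(0, 4, size=ilen).astype(np.uint8)
                parts.append(insert)
                events.append(
                    TruthEvent(chrom, pos, "ins", "-", _kmers.decode(insert))
                )
                cursor = pos
            else:
                end = min(pos + ilen, length)
                parts.append(mutated[cursor:pos])
                events.append(
                    TruthEvent(chrom, pos, "del", seq[pos:end], "-")
                )
                cursor = end
        parts.append(mutated[cursor:])
        out = np.concatenate(parts) if parts else mutated
        target[chrom] = _decode_with_n(out, n_mask, codes, seq)
    events.sort(key=lambda e: (e.chrom, e.pos))
    return Genome(target), events


def _decode_with_n(out: np.ndarray, n_mask: np.ndarray, codes: np.ndarray, seq: str) -> str:
    if not n_mask.any():
        return _kmers.decode(out)
    # N positions carry code 4 through the arithmetic; rebuild via masking
    chars = np.frombuffer(_kmers.decode(np.minimum(out, 3)).encode(), dtype=np.uint8).copy()
    chars[out >= 4] = ord("N")
    return chars.tobytes().decode()


def realized_divergence(events: Sequence[TruthEvent], genome: Genome) -> float:
    """Edit operations (SNPs + inserted + deleted bases) per reference base."""
    ops = 0
    for e in events:
        if e.type == "snp":
            ops += 1
        elif e.type == "ins":
            ops += len(e.alt_allele)
        else:
            ops += len(e.ref_allele)
    return ops / genome.total_length


def write_truth_log(events: Sequence[TruthEvent], path) -> None:
    """Serialize the truth log as TSV: chrom, pos, type, ref, alt."""
    with open(path, "w") as fh:
        fh.write("ref_chrom\tref_pos\ttype\tref_allele\talt_allele\n")
        for e in events:
            fh.write(f"{e.chrom}\t{e.pos}\t{e.type}\t{e.ref_allele}\t{e.alt_allele}\n")


def simulate_reads(target: Genome, params: ReadSimParams) -> Iterator[ReadPair]:
    """Simulate paired-end reads from uniformly placed fragments.

    Fragment lengths are normal(mean, sd), clipped to at least the read
    length; mate 1 reads the fragment start on the forward strand, mate 2
    the reverse complement of the fragment end. Base errors are i.i.d.
    substitutions at ``base_error_rate``. Chromosomes shorter than
    ``fragment_mean + 4 * fragment_sd`` are skipped with a warning.
    Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    min_len = params.fragment_mean + 4.0 * params.fragment_sd
    chroms = []
    for name, seq in target.items():
        if len(seq) < min_len:
            warnings.warn(
                f"chromosome {name!r} (len {len(seq)}) shorter than "
                f"fragment_mean + 4*sd; skipped for read simulation",
                stacklevel=2,
            )
        else:
            chroms.append((name, _kmers.encode(seq)))
    if not chroms or params.n_pairs == 0:
        return
    weights = np.array([c[1].size for c in chroms], dtype=float)
    weights /= weights.sum()
    rl = params.read_length
    qual = np.full(rl, params.quality, dtype=np.uint8)

    chrom_draw = rng.choice(len(chroms), size=params.n_pairs, p=weights)
    frags = np.rint(rng.normal(params.fragment_mean, params.fragment_sd, params.n_pairs))
    frags = np.maximum(frags, rl).astype(np.int64)
    u_start = rng.random(params.n_pairs)
    for i in range(params.n_pairs):
        name, codes = chroms[chrom_draw[i]]
        frag = min(int(frags[i]), codes.size)
        start = int(u_start[i] * (codes.size - frag + 1))
        m1 = codes[start : start + rl].copy()
        m2 = (codes[start + frag - rl : start + frag][::-1] ^ 3) & 3  # revcomp
        m2 = m2.copy()
        if params.base_error_rate > 0.0:
            for mate in (m1, m2):
                err = np.nonzero(rng.random(rl) < params.base_error_rate)[0]
                if err.size:
                    mate[err] = (mate[err] + rng.integers(1, 4, err.size).astype(np.uint8)) % 4
        yield ReadPair(
            id=f"sim|{name}|{start}|{i}",
            mate1_seq=_kmers.decode(m1),
            mate2_seq=_kmers.decode(m2),
            mate1_qual=qual,
            mate2_qual=qual,
        )
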