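"""Core value types shared across the pipeline.

These are re-exported from the public modules (:mod:`record_asm.io_formats`,
:mod:`record_asm.pseudoreads`, :mod:`record_asm.assembly`); user code should
import them from there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file did not conform to the expected text format."""


@dataclass
class Genome:
    """An ordered collection of named chromosomes of uppercase DNA text.

    Sequences are normalized to uppercase on construction and restricted to
    the alphabet {A, C, G, T, N}. Used for the reference, the (simulated)
    target, and the edited reference alike.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("a genome must contain at least one chromosome")
        normalized: dict[str, str] = {}
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-IUPAC residues: "
                    f"{sorted(bad)}"
                )
            normalized[name] = seq
        self.sequences = normalized

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def items(self):
        return self.sequences.items()

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class ReadPair:
    """A paired-end read: two mates with per-base Phred quality values.

    Covers both experimental (simulated) reads and pseudoreads cut from the
    reference.
    """

    id: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: np.ndarray
    mate2_qual: np.ndarray

    def __post_init__(self) -> None:
        self.mate1_qual = np.asarray(self.mate1_qual, dtype=np.uint8)
        self.mate2_qual = np.asarray(self.mate2_qual, dtype=np.uint8)
        if len(self.mate1_seq) != self.mate1_qual.size:
            raise ValueError(f"read {self.id}: mate 1 sequence/quality length mismatch")
        if len(self.mate2_seq) != self.mate2_qual.size:
            raise ValueError(f"read {self.id}: mate 2 sequence/quality length mismatch")


@dataclass
class Contig:
    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ContigSet:
    """Ordered list of contigs with unique ids."""

    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("contig ids must be unique")

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __bool__(self) -> bool:
        return bool(self.contigs)

    def get(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    @property
    def lengths(self) -> list[int]:
        return [len(c) for c in self.contigs]

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass
class MappingRecord:
    """One alignment of a contig (sub)segment to a reference interval.

    Coordinates are 0-based half-open on both the reference and the contig.
    ``idy_ref`` is the percent identity of the aligned segment pair and ``L``
    the length of the mapped contig segment — the two quantities combined by
    the Q_map score.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    contig_id: str
    contig_start: int
    contig_end: int
    strand: str
    idy_ref: float
    L: int

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError("reference interval must be non-empty (start < end)")
        if self.contig_start >= self.contig_end:
            raise ValueError("contig interval must be non-empty (start < end)")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.L != self.contig_end - self.contig_start:
            raise ValueError("L must equal contig_end - contig_start")
        if not 0.0 <= self.idy_ref <= 100.0:
            raise ValueError("idy_ref must lie in [0, 100]")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N} (involution)."""
    unknown = set(seq.upper()) - DNA_ALPHABET
    if unknown:
        raise ValueError(f"cannot reverse-complement characters {sorted(unknown)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]
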