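"""Readers and writers for FASTA, paired FASTQ and show-coords tab files.

All coordinates are 0-based half-open inside the package; the MUMmer-style
coords dialect on disk is 1-based inclusive with query coordinates reversed
on the minus strand, and is converted at this boundary.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from ._model import (
    DNA_ALPHABET,
    Contig,
    ContigSet,
    FormatError,
    Genome,
    MappingRecord,
    ReadPair,
)

__all__ = [
    "Genome",
    "MappingRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_contigs",
    "write_contigs",
    "read_paired_fastq",
    "write_fastq",
    "parse_coords",
    "write_coords",
]

FASTA_WIDTH = 70
#: Sanger/Phred+33 quality range
QUAL_MIN, QUAL_MAX = 0, 93


def read_fasta(path: str | os.PathLike) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Record order is preserved, sequences are folded to uppercase, and header
    text after the first whitespace is dropped from the name. Duplicate
    names, residues outside {A,C,G,T,N} and empty files raise
    :class:`FormatError` naming the offending line.
    """
    sequences: dict[str, list[str]] = {}
    name: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in sequences:
                    raise FormatError(f"{path}:{lineno}: duplicate sequence name {name!r}")
                sequences[name] = []
            else:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: sequence data before any header")
                chunk = line.upper()
                bad = set(chunk) - DNA_ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: non-IUPAC residues {sorted(bad)}"
                    )
                sequences[name].append(chunk)
    if not sequences:
        raise FormatError(f"{path}: empty FASTA file")
    for nm, chunks in sequences.items():
        if not chunks:
            raise FormatError(f"{path}: sequence {nm!r} has no residues")
    return Genome({nm: "".join(chunks) for nm, chunks in sequences.items()})


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = FASTA_WIDTH) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_contigs(path: str | os.PathLike) -> ContigSet:
    """Read a contig FASTA (same dialect as :func:`read_fasta`)."""
    genome = read_fasta(path)
    return ContigSet([Contig(name, seq) for name, seq in genome.items()])


def write_contigs(contigs: ContigSet, path: str | os.PathLike, width: int = FASTA_WIDTH) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.id}\n")
            for i in range(0, len(contig.seq), width):
                fh.write(contig.seq[i : i + width] + "\n")


def write_fastq(
    pairs: Iterable[ReadPair],
    path_1: str | os.PathLike,
    path_2: str | os.PathLike,
) -> int:
    """Write paired reads as two Sanger-encoded (Phred+33) FASTQ files.

    Mate 1 goes to ``path_1`` and mate 2 to ``path_2`` in the same order,
    with ids suffixed ``/1`` and ``/2``. Returns the number of pairs
    written. Round-trips bit-exactly through :func:`read_paired_fastq`.
    """
    n = 0
    with open(path_1, "w") as f1, open(path_2, "w") as f2:
        for pair in pairs:
            f1.write(_fastq_record(pair.id + "/1", pair.mate1_seq, pair.mate1_qual))
            f2.write(_fastq_record(pair.id + "/2", pair.mate2_seq, pair.mate2_qual))
            n += 1
    return n


def _fastq_record(rid: str, seq: str, qual: np.ndarray) -> str:
    q = np.asarray(qual)
    if q.size and (int(q.min()) < QUAL_MIN or int(q.max()) > QUAL_MAX):
        raise ValueError(
            f"read {rid}: quality values must lie in [{QUAL_MIN}, {QUAL_MAX}]"
        )
    qstr = (q.astype(np.uint8) + 33).tobytes().decode("ascii")
    return f"@{rid}\n{seq}\n+\n{qstr}\n"


def read_paired_fastq(
    path_1: str | os.PathLike, path_2: str | os.PathLike
) -> Iterator[ReadPair]:
    """Stream :class:`ReadPair` objects from two mate files (Phred+33)."""
    it1 = SeqIO.parse(str(path_1), "fastq")
    it2 = SeqIO.parse(str(path_2), "fastq")
    for rec1, rec2 in zip(it1, it2, strict=True):
        rid1 = _strip_mate_suffix(rec1.id)
        rid2 = _strip_mate_suffix(rec2.id)
        if rid1 != rid2:
            raise FormatError(f"mate id mismatch: {rec1.id!r} vs {rec2.id!r}")
        yield ReadPair(
            id=rid1,
            mate1_seq=str(rec1.seq).upper(),
            mate2_seq=str(rec2.seq).upper(),
            mate1_qual=np.asarray(rec1.letter_annotations["phred_quality"], dtype=np.uint8),
            mate2_qual=np.asarray(rec2.letter_annotations["phred_quality"], dtype=np.uint8),
        )


def _strip_mate_suffix(rid: str) -> str:
    return rid[:-2] if rid.endswith(("/1", "/2")) else rid


_COORDS_COLUMNS = 9  # S1 E1 S2 E2 LEN1 LEN2 %IDY ref query


def parse_coords(path: str | os.PathLike) -> list[MappingRecord]:
    """Parse a show-coords tab dialect file into mapping records.

    Expected columns per line: ``S1 E1 S2 E2 LEN1 LEN2 %IDY ref query``
    with 1-based inclusive coordinates; query coordinates reversed
    (S2 > E2) signal the minus strand. An empty file yields an empty list.
    """
    records: list[MappingRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != _COORDS_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_COORDS_COLUMNS} tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                s1, e1, s2, e2 = (int(x) for x in fields[:4])
                idy = float(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if s1 > e1:
                raise FormatError(f"{path}:{lineno}: reference start {s1} > end {e1}")
            ref_name, query_name = fields[7], fields[8]
            if s2 <= e2:
                strand, cstart, cend = "+", s2 - 1, e2
            else:
                strand, cstart, cend = "-", e2 - 1, s2
            records.append(
                MappingRecord(
                    ref_chrom=ref_name,
                    ref_start=s1 - 1,
                    ref_end=e1,
                    contig_id=query_name,
                    contig_start=cstart,
                    contig_end=cend,
                    strand=strand,
                    idy_ref=idy,
                    L=cend - cstart,
                )
            )
    return records


def write_coords(records: Iterable[MappingRecord], path: str | os.PathLike) -> None:
    """Write mapping records in the show-coords tab dialect (inverse of
    :func:`parse_coords`)."""
    with open(path, "w") as fh:
        for r in records:
            if r.strand == "+":
                s2, e2 = r.contig_start + 1, r.contig_end
            else:
                s2, e2 = r.contig_end, r.contig_start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.ref_start + 1,
                        r.ref_end,
                        s2,
                        e2,
                        r.ref_end - r.ref_start,
                        r.L,
                        f"{r.idy_ref:.2f}",
                        r.ref_chrom,
                        r.contig_id,
                    )
                )
                + "\n"
            )
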