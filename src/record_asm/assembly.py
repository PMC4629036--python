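"""Quality-aware de Bruijn micro-assembler and external-assembler adapter.

The internal assembler co-assembles experimental reads and pseudoreads. It
counts canonical k-mers over both mates of every pair (windows containing N
are skipped), drops k-mers below a solidity threshold, and extends contigs
greedily from high-coverage seeds. At every extension step the next base is
chosen by a quality-weighted vote: the candidate base whose supporting read
bases carry the highest summed Phred quality wins (exact ties break to the
alphabetically earliest base). Because experimental bases (Q40 by default in
simulation) outweigh Q10 pseudoread bases, the contigs follow the sequenced
genome wherever reads cover it and fall back to the reference elsewhere.
The losing branch of such a vote survives only as a short spur, which the
``min_contig_len`` filter removes.

The assembler is deliberately minimal — no bubble popping beyond the vote,
no scaffolding from pair information — because the pipeline treats the
assembler as a swappable component (see :func:`run_external_assembler`).
"""

from __future__ import annotations

import shlex
import subprocess
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _kmers
from ._model import Contig, ContigSet, ReadPair

__all__ = [
    "AssemblerConfig",
    "Contig",
    "ContigSet",
    "assemble",
    "run_external_assembler",
    "ExternalAssemblerError",
]


@dataclass
class AssemblerConfig:
    """Internal assembler parameters.

    k
        odd k-mer size (default 21, suitable for 70-100 bp reads).
    min_contig_len
        shortest contig emitted; also removes losing-branch spurs.
    min_kmer_count
        solid-k-mer threshold. 1 by default: pseudoreads guarantee at least
        one observation everywhere, and error k-mers are tolerable at this
        scale. Raise it for noisy read sets.
    """

    k: int = 21
    min_contig_len: int = 100
    min_kmer_count: int = 1

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError("k must be odd")
        if not 11 <= self.k <= 31:
            raise ValueError("k must lie in [11, 31]")
        if self.min_contig_len < self.k:
            raise ValueError("min_contig_len must be >= k")
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")


_FLUSH_BASES = 8_000_000


class _KmerTally:
    """Streaming canonical k-mer counter with per-end quality weights.

    For every k-mer occurrence the quality of its first and last base is
    accumulated (in canonical orientation), which is exactly the evidence
    needed for the per-base extension vote.
    """

    def __init__(self, k: int) -> None:
        self.k = k
        self._seq_parts: list[str] = []
        self._qual_parts: list[np.ndarray] = []
        self._pending = 0
        self._chunks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        self._sep_qual = np.zeros(1, dtype=np.uint8)

    def add(self, seq: str, qual: np.ndarray) -> None:
        if len(seq) < self.k:
            return
        self._seq_parts.append(seq)
        self._seq_parts.append("N")  # separator: no window crosses reads
        self._qual_parts.append(np.asarray(qual, dtype=np.uint8))
        self._qual_parts.append(self._sep_qual)
        self._pending += len(seq) + 1
        if self._pending >= _FLUSH_BASES:
            self._flush()

    def _flush(self) -> None:
        if not self._seq_parts:
            return
        codes = _kmers.encode("".join(self._seq_parts))
        quals = np.concatenate(self._qual_parts)
        self._seq_parts, self._qual_parts, self._pending = [], [], 0
        k = self.k
        fwd, rc, valid = _kmers.kmer_windows(codes, k)
        fwd, rc = fwd[valid], rc[valid]
        q_start = quals[: quals.size - k + 1][valid]
        q_end = quals[k - 1 :][valid]
        is_fwd = fwd <= rc
        canon = np.where(is_fwd, fwd, rc)
        first_q = np.where(is_fwd, q_start, q_end)
        last_q = np.where(is_fwd, q_end, q_start)
        self._chunks.append((canon, first_q.astype(np.uint32), last_q.astype(np.uint32)))

    def finalize(self, min_count: int):
        self._flush()
        if not self._chunks:
            empty = np.zeros(0, dtype=np.uint64)
            return empty, empty.astype(np.int64), empty.astype(np.float64), empty.astype(np.float64)
        canon = np.concatenate([c[0] for c in self._chunks])
        first_q = np.concatenate([c[1] for c in self._chunks])
        last_q = np.concatenate([c[2] for c in self._chunks])
        self._chunks = []
        uniq, inverse = np.unique(canon, return_inverse=True)
        counts = np.bincount(inverse, minlength=uniq.size)
        first_w = np.bincount(inverse, weights=first_q, minlength=uniq.size)
        last_w = np.bincount(inverse, weights=last_q, minlength=uniq.size)
        if min_count > 1:
            keep = counts >= min_count
            uniq, counts = uniq[keep], counts[keep]
            first_w, last_w = first_w[keep], last_w[keep]
        return uniq, counts, first_w, last_w


def assemble(reads: Iterable[ReadPair], config: AssemblerConfig | None = None) -> ContigSet:
    """Co-assemble read pairs (experimental and pseudo) into contigs.

    Deterministic: the contig set depends only on the multiset of reads and
    the configuration, not on input order.
    """
    if config is None:
        config = AssemblerConfig()
    k = config.k
    tally = _KmerTally(k)
    n_reads = n_short = 0
    for pair in reads:
        for seq, qual in ((pair.mate1_seq, pair.mate1_qual), (pair.mate2_seq, pair.mate2_qual)):
            n_reads += 1
            if len(seq) < k:
                n_short += 1
            else:
                tally.add(seq, qual)
    if n_reads == 0 or n_short == n_reads:
        if n_reads:
            warnings.warn(
                f"all {n_reads} reads are shorter than k={k}; no contigs assembled",
                stacklevel=2,
            )
        return ContigSet([])

    uniq, counts, first_w, last_w = tally.finalize(config.min_kmer_count)
    if uniq.size == 0:
        return ContigSet([])
    index = {km: i for i, km in enumerate(uniq.tolist())}
    first_w_l = first_w.tolist()
    last_w_l = last_w.tolist()
    used = np.zeros(uniq.size, dtype=bool)

    # seeds in decreasing coverage order so well-supported paths are laid
    # down before losing-branch spurs; k-mer value breaks ties for determinism
    seed_order = np.lexsort((uniq, -counts))
    mask = (1 << (2 * k)) - 1
    hi_shift = 2 * (k - 1)
    uniq_list = uniq.tolist()

    contigs: list[Contig] = []
    for si in seed_order.tolist():
        if used[si]:
            continue
        used[si] = True
        seed = uniq_list[si]
        codes = _extend_right(seed, k, mask, hi_shift, index, used, first_w_l, last_w_l)
        # turn around: extend the other direction on the reverse complement
        rc_codes = [3 ^ c for c in reversed(codes)]
        end_kmer = 0
        for c in rc_codes[-k:]:
            end_kmer = ((end_kmer << 2) | c) & mask
        full = _extend_right(
            end_kmer, k, mask, hi_shift, index, used, first_w_l, last_w_l, prefix=rc_codes
        )
        if len(full) >= config.min_contig_len:
            contigs.append(Contig(id="", seq=_kmers.decode(np.array(full, dtype=np.uint8))))

    for i, contig in enumerate(contigs):
        contig.id = f"ctg_{i:05d}"
    return ContigSet(contigs)


def _extend_right(
    kmer: int,
    k: int,
    mask: int,
    hi_shift: int,
    index: dict[int, int],
    used: np.ndarray,
    first_w: Sequence[float],
    last_w: Sequence[float],
    prefix: list[int] | None = None,
) -> list[int]:
    """Greedy rightward walk from ``kmer``; returns base codes including it."""
    if prefix is None:
        codes = [(kmer >> (2 * (k - 1 - i))) & 3 for i in range(k)]
    else:
        codes = prefix
    fwd = kmer
    rcomp = _kmers.revcomp_int(kmer, k)
    while True:
        best_b = -1
        best_w = -1.0
        best = None
        base = (fwd << 2) & mask
        for b in range(4):
            nf = base | b
            nr = (rcomp >> 2) | ((3 ^ b) << hi_shift)
            canon = nf if nf <= nr else nr
            idx = index.get(canon)
            if idx is None or used[idx]:
                continue
            w = last_w[idx] if canon == nf else first_w[idx]
            if w > best_w:
                best_w = w
                best_b = b
                best = (nf, nr, idx)
        if best is None:
            return codes
        fwd, rcomp, idx = best
        used[idx] = True
        codes.append(best_b)


class ExternalAssemblerError(RuntimeError):
    """The external assembler binary is missing or failed."""


def run_external_assembler(
    cmd_template: str,
    reads_paths: Sequence[str | Path],
    workdir: str | Path,
    dry_run: bool = False,
) -> ContigSet | str:
    """Run an external assembler and collect its contig FASTA.

    ``cmd_template`` may contain ``{reads}`` (space-joined read paths) and
    ``{out}`` (the contig FASTA path the command must produce, inside
    ``workdir``). With ``dry_run=True`` the fully substituted command string
    is returned without executing anything.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    out_path = workdir / "contigs.fa"
    cmd = cmd_template.format(
        reads=" ".join(str(p) for p in reads_paths), out=str(out_path)
    )
    if dry_run:
        return cmd
    try:
        proc = subprocess.run(
            shlex.split(cmd), cwd=workdir, capture_output=True, text=True
        )
    except FileNotFoundError as exc:
        raise ExternalAssemblerError(f"assembler binary not found: {exc}") from exc
    if proc.returncode != 0:
        raise ExternalAssemblerError(
            f"external assembler exited with {proc.returncode}: {proc.stderr[-500:]}"
        )
    if not out_path.exists():
        raise ExternalAssemblerError(f"external assembler produced no {out_path}")
    from .io_formats import read_contigs

    return read_contigs(out_path)
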