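"""Uniformly tiled, low-quality paired pseudoreads cut from the reference.

Pseudoreads give the assembler guaranteed uniform coverage of the reference
so experimental reads can be joined into long contigs even where their own
coverage is thin. Their deliberately low quality (default Q10) lets
high-quality experimental bases outvote them wherever the sequenced genome
differs from the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ._model import Genome, ReadPair, reverse_complement

__all__ = [
    "PseudoreadParams",
    "ReadPair",
    "generate_pseudoreads",
    "reverse_complement",
    "pair_count",
]


@dataclass
class PseudoreadParams:
    """Tiling parameters.

    m
        read length of each mate (bases).
    n
        step between successive mate-1 start positions (bases).
    d
        outer fragment length: distance from mate-1 start to mate-2 window
        end. Mate 2 is the reverse complement of the last ``m`` bases of the
        fragment, giving a long-insert pair with a ``d - 2m`` inner gap.
    q
        constant Phred quality assigned to every pseudoread base.
    """

    m: int = 100
    n: int = 30
    d: int = 1000
    q: int = 10

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("read length m must be >= 1")
        if self.n < 1:
            raise ValueError("step n must be >= 1")
        if self.d < self.m:
            raise ValueError("fragment length d must be >= read length m")
        if not 0 <= self.q <= 93:
            raise ValueError("quality q must lie in the Phred range [0, 93]")


def pair_count(chrom_length: int, params: PseudoreadParams) -> int:
    """Number of pairs emitted from one chromosome:
    ``floor((Len - d)/n) + 1`` when ``Len >= d``, else 0."""
    if chrom_length < params.d:
        return 0
    return (chrom_length - params.d) // params.n + 1


def generate_pseudoreads(
    genome: Genome, params: PseudoreadParams | None = None
) -> Iterator[ReadPair]:
    """Tile every chromosome at step ``n`` into paired pseudoreads.

    For each start ``p`` in {0, n, 2n, ...} with ``p + d <= Len``, mate 1 is
    ``chrom[p : p+m]`` taken directly from the reference and mate 2 the
    reverse complement of ``chrom[p+d-m : p+d]``. Pairs whose fragment would
    overrun the chromosome are skipped entirely, so every emitted read has
    full length. Generation is deterministic; ids are
    ``pseudo|<chrom>|<p>``.
    """
    if params is None:
        params = PseudoreadParams()
    m, n, d, q = params.m, params.n, params.d, params.q
    for chrom, seq in genome.items():
        length = len(seq)
        qual = np.full(m, q, dtype=np.uint8)
        for p in range(0, length - d + 1, n):
            mate1 = seq[p : p + m]
            mate2 = reverse_complement(seq[p + d - m : p + d])
            yield ReadPair(
                id=f"pseudo|{chrom}|{p}",
                mate1_seq=mate1,
                mate2_seq=mate2,
                mate1_qual=qual,
                mate2_qual=qual,
            )
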