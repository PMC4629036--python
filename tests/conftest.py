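import numpy as np
import pytest

from record_asm._model import Contig, ContigSet, Genome, MappingRecord, ReadPair
from record_asm.synthetic_data import random_genome


def make_pair(rid, m1, m2, q1=40, q2=40):
    """ReadPair with constant per-mate qualities."""
    return ReadPair(
        id=rid,
        mate1_seq=m1,
        mate2_seq=m2,
        mate1_qual=np.full(len(m1), q1, dtype=np.uint8),
        mate2_qual=np.full(len(m2), q2, dtype=np.uint8),
    )


def tiling_pairs(seq, read_len=70, step=1, quality=40):
    """Error-free pairs tiling ``seq`` end to end (mate 2 reads the reverse
    complement of the window immediately downstream of mate 1)."""
    from record_asm.pseudoreads import reverse_complement

    frag = 2 * read_len
    pairs = []
    for p in range(0, len(seq) - frag + 1, step):
        pairs.append(
            make_pair(
                f"t{p}",
                seq[p : p + read_len],
                reverse_complement(seq[p + frag - read_len : p + frag]),
                quality,
                quality,
            )
        )
    return pairs


def mapping(
    contig_id="c",
    ref_chrom="chr1",
    ref_start=0,
    ref_end=100,
    contig_start=0,
    contig_end=100,
    strand="+",
    idy=99.0,
):
    return MappingRecord(
        ref_chrom=ref_chrom,
        ref_start=ref_start,
        ref_end=ref_end,
        contig_id=contig_id,
        contig_start=contig_start,
        contig_end=contig_end,
        strand=strand,
        idy_ref=idy,
        L=contig_end - contig_start,
    )


@pytest.fixture(scope="session")
def small_genome():
    """10 kb single-chromosome random genome."""
    return random_genome([10_000], gc=0.5, seed=42)


@pytest.fixture(scope="session")
def repeat_genome():
    """Reference with an exact duplicated 1 kb block (ambiguity fixture)."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    block = "".join(rng.choice(bases, 1000))
    left = "".join(rng.choice(bases, 4000))
    mid = "".join(rng.choice(bases, 3000))
    right = "".join(rng.choice(bases, 4000))
    return Genome({"chr1": left + block + mid + block + right})


@pytest.fixture(scope="session")
def repeat_block_span():
    """(first copy interval, second copy interval) of the duplicated block."""
    return (4000, 5000), (8000, 9000)


def contigs_from(genome, intervals, prefix="ctg"):
    """Cut contigs out of a genome: intervals = [(chrom, start, end), ...]."""
    return ContigSet(
        [
            Contig(f"{prefix}{i}", genome[chrom][s:e])
            for i, (chrom, s, e) in enumerate(intervals)
        ]
    )
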