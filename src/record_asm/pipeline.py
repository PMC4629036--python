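"""End-to-end orchestration: pseudoreads -> co-assembly -> mapping -> editing.

:func:`run_record` is the disk-oriented pipeline used by the CLI: it
persists every intermediate artifact (pseudoread FASTQ, contig FASTA,
mappings in coords dialect, edited reference FASTA, JSON reports) and logs
per-stage timing and checksums. :func:`simulate_study` is the in-memory
variant used to replicate the simulation study: it fabricates a reference,
an evolved target and reads, runs the pipeline, and measures contig and
edited-reference accuracy against the known target.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from ._model import ContigSet, Genome, ReadPair
from .assembly import AssemblerConfig, assemble
from .contig_mapping import (
    MIN_IDY,
    MIN_MATCH_LEN,
    ambiguous_fraction,
    map_contigs,
)
from .evaluation import EvaluationReport, evaluate_assembly, idy_and_error
from .io_formats import (
    read_fasta,
    read_paired_fastq,
    write_contigs,
    write_coords,
    write_fasta,
    write_fastq,
)
from .pseudoreads import PseudoreadParams, generate_pseudoreads
from .reference_editing import (
    EditReport,
    resolve_overlaps,
    select_best_mappings,
    splice_reference,
)
from .synthetic_data import (
    EvolutionParams,
    ReadSimParams,
    evolve,
    random_genome,
    simulate_reads,
)

__all__ = [
    "PipelineConfig",
    "PipelineConfigError",
    "RecordResult",
    "run_record",
    "simulate_study",
    "StudyResult",
]

logger = logging.getLogger("record")


class PipelineConfigError(ValueError):
    """The pipeline configuration references missing inputs."""


@dataclass
class PipelineConfig:
    reference: Path
    reads_1: Path
    reads_2: Path
    outdir: Path
    target: Path | None = None  # simulation mode: evaluate against this
    pseudoread_params: PseudoreadParams = field(default_factory=PseudoreadParams)
    assembler: AssemblerConfig = field(default_factory=AssemblerConfig)
    min_match_len: int = MIN_MATCH_LEN
    min_idy: float = MIN_IDY
    compute_identity: bool = True

    def validate(self) -> None:
        for label, path in (
            ("reference", self.reference),
            ("reads_1", self.reads_1),
            ("reads_2", self.reads_2),
            ("target", self.target),
        ):
            if path is not None and not Path(path).exists():
                raise PipelineConfigError(f"{label} file not found: {path}")


@dataclass
class RecordResult:
    edited: Genome
    edit_report: EditReport
    contigs: ContigSet
    evaluation: EvaluationReport | None = None


def _checksum(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: started", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.1fs", self.name, dt)
        else:
            logger.error("stage %s: FAILED after %.1fs (%s)", self.name, dt, exc)
        return False


def _tee_pairs(pairs: Iterable[ReadPair], sink: list[ReadPair]) -> Iterator[ReadPair]:
    for p in pairs:
        sink.append(p)
        yield p


def run_record(config: PipelineConfig) -> RecordResult:
    """Run the full pipeline from files on disk, persisting every artifact."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _Stage("load-inputs"):
        reference = read_fasta(config.reference)

    with _Stage("pseudoreads"):
        pseudo: list[ReadPair] = list(
            generate_pseudoreads(reference, config.pseudoread_params)
        )
        p1, p2 = outdir / "pseudo_1.fq", outdir / "pseudo_2.fq"
        write_fastq(pseudo, p1, p2)
        logger.info("pseudoreads: %d pairs (%s %s)", len(pseudo), _checksum(p1), _checksum(p2))

    with _Stage("assemble"):
        reads = read_paired_fastq(config.reads_1, config.reads_2)
        contigs = assemble(itertools.chain(iter(pseudo), reads), config.assembler)
        contigs_path = outdir / "contigs.fa"
        write_contigs(contigs, contigs_path)
        logger.info("assembled %d contigs (%s)", len(contigs), _checksum(contigs_path))

    with _Stage("map"):
        mappings = map_contigs(
            contigs, reference, min_match_len=config.min_match_len, min_idy=config.min_idy
        )
        write_coords(mappings, outdir / "mappings.tsv")
        logger.info(
            "%d mappings, ambiguous fraction %.3f",
            len(mappings),
            ambiguous_fraction(mappings),
        )

    with _Stage("edit"):
        selected = select_best_mappings(mappings)
        placements = resolve_overlaps(selected)
        edited, edit_report = splice_reference(
            reference, placements, contigs, compute_identity=config.compute_identity
        )
        write_fasta(edited, outdir / "edited.fa")
        (outdir / "edit_report.json").write_text(edit_report.to_json())

    evaluation = None
    if config.target is not None:
        with _Stage("evaluate"):
            target = read_fasta(config.target)
            evaluation = evaluate_assembly(contigs, target)
            (outdir / "evaluation.json").write_text(evaluation.to_json())

    return RecordResult(edited, edit_report, contigs, evaluation)


@dataclass
class StudyResult:
    """Accuracy measurements from one simulated replication run."""

    contig_error: float  # 100 - weighted identity of contigs vs target
    contig_idy: float
    idy_reference_vs_target: float
    idy_edited_vs_target: float
    n_contigs: int
    n50: int
    total_contig_length: int
    edit_report: EditReport
    realized_divergence: float


def simulate_study(
    seed: int,
    genome_length: int = 1_000_000,
    n_chrom: int = 3,
    n_pairs: int = 110_000,
    read_length: int = 70,
    snp_rate: float = 0.01,
    ins_rate: float = 5e-4,
    del_rate: float = 5e-4,
    k: int = 21,
) -> StudyResult:
    """One scaled-down replication of the simulation study, in memory.

    Generates a multi-chromosome random reference, evolves a target at the
    configured divergence, simulates error-free paired reads from the
    target, runs the full pipeline (pseudoreads at the default
    m=100/n=30/d=1000/q=10, internal assembly, mapping, editing), and
    measures assembly and edited-reference accuracy against the target.
    """
    from .synthetic_data import realized_divergence

    base = max(0, int(seed)) % (2**31 - 10_000)
    per = genome_length // n_chrom
    lengths = [per] * (n_chrom - 1) + [genome_length - per * (n_chrom - 1)]
    reference = random_genome(lengths, seed=base)
    target, events = evolve(
        reference,
        EvolutionParams(
            snp_rate=snp_rate, ins_rate=ins_rate, del_rate=del_rate, seed=base + 1
        ),
    )
    reads = simulate_reads(
        target, ReadSimParams(n_pairs=n_pairs, read_length=read_length, seed=base + 2)
    )
    pseudo = generate_pseudoreads(reference, PseudoreadParams())
    contigs = assemble(
        itertools.chain(pseudo, reads), AssemblerConfig(k=k, min_contig_len=100)
    )

    contig_idy, contig_error = idy_and_error(contigs, target)
    mappings = map_contigs(contigs, reference)
    selected = select_best_mappings(mappings)
    placements = resolve_overlaps(selected)
    edited, edit_report = splice_reference(
        reference, placements, contigs, compute_identity=False
    )
    idy_edit, _ = idy_and_error(edited, target)
    idy_ref, _ = idy_and_error(reference, target)

    from .evaluation import n50 as _n50

    return StudyResult(
        contig_error=contig_error,
        contig_idy=contig_idy,
        idy_reference_vs_target=idy_ref,
        idy_edited_vs_target=idy_edit,
        n_contigs=len(contigs),
        n50=_n50(contigs) if len(contigs) else 0,
        total_contig_length=contigs.total_length,
        edit_report=edit_report,
        realized_divergence=realized_divergence(events, reference),
    )
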