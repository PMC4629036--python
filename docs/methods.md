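# Methods

## Problem setting and model

The pipeline reconstructs the genome of a sample that is *very closely
related* (on the order of 1% sequence divergence) to a known reference:
mutants, cell lines, individuals of a sequenced species. It assumes
divergence is dominated by point substitutions and short indels; it makes
no attempt to recover rearrangements, large insertions, or copy-number
changes, and the reference is used directly to determine the order and
orientation of the assembly (no scaffolding from read pairs). Because a de
novo assembler runs inside the pipeline, it is intended for small to
mid-sized genomes, not human-scale ones.

## Pipeline stages

### Pseudoreads

Paired pseudoreads are cut deterministically from the reference: mate-1
windows of length *m* start at 0, *n*, 2*n*, …; mate 2 is the reverse
complement of the last *m* bases of the *d*-long fragment starting at the
same position. Defaults: *m* = 100 bases, *n* = 30 bases (per-base
pseudoread coverage ≈ 2·*m*/*n* ≈ 6.7×), *d* = 1000 bases, quality
*q* = 10 (Phred). Interpretation of *d* as the *outer* fragment length
(mate-2 window = [p+d−m, p+d)) is a design choice; with the defaults it
yields a long-insert pair with an 800-base inner gap. Pairs whose fragment
would overrun the chromosome are skipped rather than truncated, so all
pseudoreads have full length; the cost is at most *d* bases of lost tail
tiling per chromosome. Windows containing N are emitted unchanged — the
assembler refuses to form k-mers across N, so they are harmless downstream.

### Assembly

The built-in assembler is a deliberately minimal quality-aware de Bruijn
graph walker:

- Canonical k-mers (lexicographic minimum of k-mer and reverse complement)
  are counted over both mates of every pair; windows containing N are
  skipped; k-mers with count < `min_kmer_count` (default 1) are dropped.
  The default of 1 is appropriate for the error-free simulated reads this
  package generates, where pseudoreads already guarantee ≥1 coverage
  everywhere; noisy read sets should raise it.
- For every k-mer the summed Phred quality of its first and last base is
  recorded. During contig extension, the candidate next bases compete by
  this summed quality — exactly a per-base quality-weighted majority vote,
  so 3 experimental bases at Q40 (weight 120) outvote 5 pseudoread bases at
  Q10 (weight 50). Ties break to the alphabetically earliest base.
- Extension is greedy from seeds processed in decreasing k-mer count order
  (ties by k-mer value), each k-mer usable once. Seeding high-coverage
  k-mers first lays down well-supported paths before losing-branch spurs;
  the losing allele of a vote survives only as a spur of at most ~2k bases,
  which the `min_contig_len` filter (default 100) removes.

Compared with a conventional unitig assembler this walker does not stop at
branch points; it resolves them by the quality vote. That is what makes the
pipeline's priority rule (experimental reads over pseudoreads) effective at
SNP positions, at the price of possible chimeric joins through long exact
repeats. At the ~1% divergence, repeat-poor scale this package targets, the
mapper recovers such events by emitting one mapping record per matched
segment. There is no bubble popping, no scaffolding, and no attempt to
reproduce the behaviour of any production assembler; the pipeline treats
the assembler as swappable, and `run_external_assembler` adapts any
command-line assembler that produces a contig FASTA.

Assembly output is deterministic given the read multiset and configuration
(independent of read order).

### Mapping and Q_map

Contigs are aligned to the reference by seed-and-extend: exact 21-mer
matches against an index of the forward reference strand (both contig
strands are queried), clustered by (chromosome, strand, diagonal band), with
band = max(20, 10% of contig length). Sparse clusters (seed density < 5% of
the spanned windows) are discarded as random collisions. Each cluster is
resolved by chaining its colinear seeds into maximal exact anchors and
aligning only the short gaps between anchors with global edit-distance
alignment (edlib); unseeded contig ends are extended by prefix alignment up
to a 400-base cap, and an end extension whose own identity falls below
`min_idy` is discarded so partially matching contigs map as segments.
Percent identity is matches over alignment columns (gaps count as columns),
reported to 2 decimals. Records shorter than `min_match_len` (default 65)
or below `min_idy` (default 90%) are suppressed; both thresholds are
CLI-exposed. Pre-computed alignments in the show-coords tab dialect can be
ingested instead, producing the same record type.

Each mapping is scored Q_map = L × idy^(ref). Per contig the
highest-scoring mapping is kept; ties break to the smaller (chromosome,
ref_start) with '+' before '−'.

### Overlap resolution and splicing

Residual overlaps between selected mappings are resolved by assigning every
reference position to the covering mapping with the largest start
coordinate: the downstream contig keeps its beginning, the upstream one is
trimmed. Fully nested overlaps split the outer placement into two flanking
segments (both retained), and 3+-way overlaps fall out of the same rule in
a single sweep. Reference columns removed by trimming are converted to
contig bases by integer (floor) proportional scaling of the mapping's
contig interval — coords-level records carry no per-column alignment, so
this is an approximation, exact for gap-free alignments. Minus-strand
segments are reverse-complemented before splicing so the edited reference
stays in reference orientation. Splicing conserves length exactly:
edited = reference − replaced + contig bases used.

### Evaluation

- N50: shortest contig in the minimal set of largest contigs covering at
  least half the assembly.
- IDY/Error: the assembly (contigs or a whole genome) is mapped to the
  target and identities of mapped segments are averaged weighted by mapped
  length; when a region maps more than once, all mappings enter the
  average. Error = 100 − IDY.
- Identical bases = IDY × TL; megabase figures are rounded half-up to two
  decimals.
- Covered target bases use the union (not sum) of mapped target intervals,
  merging adjacent half-open intervals.
- Fold coverage Cov = read_length × n_reads / genome_size.

## Synthetic data

The generator emulates a small resequencing study: i.i.d. random genomes at
a mammalian-like GC of 0.41; evolution by independent per-base events —
substitutions to a uniformly chosen different base at `snp_rate` (default
0.01), insertions and deletions at 5×10⁻⁴ each with geometric lengths of
mean 3; and paired-end reads from uniformly placed normal(500, 50)
fragments, 70 bp mates, error-free at constant Q40 by default. Every
mutation is logged with reference coordinates. All randomness flows through
explicit seeds.

What it deliberately does not emulate: genome repeat structure and
compositional heterogeneity, rearrangements and mobile elements,
instrument-specific error and quality profiles, GC-dependent coverage bias,
and chimeric fragments. Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under point-mutation-scale divergence with
clean reads; they do not bound its accuracy on repeat-rich genomes or noisy
libraries, where the assembler's minimal design (greedy branch votes,
count-1 k-mer threshold) would be the first thing to revisit.

## Scaled-down replication study

`scripts/acceptance.py` and the heavyweight acceptance test replicate the
simulation design at desk scale: a 1 Mb, 3-chromosome reference (the full
study used 30 Mb), evolved at 1% SNP + indel divergence, with 110,000
error-free 70 bp pairs (~15× coverage), pseudoread defaults, k = 21, three
seeded replicates, median contig Error reported. The 1 Mb size keeps one
replicate under a minute while leaving thousands of mutation events per
replicate; measured contig error is typically 0.05–0.15%, comfortably
inside the < 0.5% regime claimed for this method, and the edited reference
is consistently closer to the target (identity ≈ 99.6–99.8%) than the raw
reference (≈ 98.7%).

## Numerical and design choices

- All internal coordinates are 0-based half-open; the coords dialect
  (1-based inclusive, reversed query coordinates on '−') is converted at
  the I/O boundary. A 1-base minus-strand interval is unrepresentable in
  that dialect (S2 = E2 reads as forward).
- FASTQ is fixed to Sanger Phred+33, qualities 0–93; out-of-range values
  are an error, as are ambiguity codes other than N in sequence input
  (fail loudly rather than fold silently).
- Degenerate inputs: chromosomes shorter than the pseudoread fragment yield
  no pairs; reads shorter than k are skipped (a warning if *all* reads
  are); an empty mapping set makes IDY an error, not a default; N50 of an
  empty contig set is an error; "half the target unreachable" is reported
  as None rather than a number.
- Determinism everywhere: assembly is input-order independent; mapping,
  selection and overlap resolution have total tie-break orders; generators
  are seeded.

## Known limitations

- The greedy walker can weld distinct loci that share an exact k-mer; the
  mapper splits such chimeras into per-locus records, but one of the
  segments then loses the per-contig best-mapping selection, leaving that
  region of the reference unedited (visible as pct_ref below 100% even at
  full read coverage).
- Proportional contig-interval trimming is approximate in the presence of
  indels inside the trimmed region.
- Identity weighting counts multiply-mapped segments multiply; this matches
  the weighted-average definition used throughout but slightly favours
  repeated regions.
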