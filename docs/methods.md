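# Methods

## Model and assumptions

`taxalign` treats taxonomic read assignment as exact-seed anchoring followed
by bounded-error verification.  The underlying assumptions are:

- Reads are short (~150 bp) single-end sequences from coding regions of
  bacterial genomes; paired-end mates are treated as independent single-end
  reads (no fragment-level rescue).
- A read that truly originates from a reference species aligns to some
  genome of that species with a small edit distance; divergence between the
  sample organism and the reference is absorbed by the edit-distance
  threshold, not by seed inexactness (seeds are exact).
- The reference database is the universe of possible sources.  Reads from
  absent organisms either stay unassigned or hit a relative; the simulator
  quantifies only the closed-world case.

### Alignment semantics

The verification step is defined as **semi-global unit-cost edit distance**:
the whole read must align, and gaps at either end of the reference window
are free.  A local alignment under unit costs would degenerate to trivial
empty alignments, while a threshold on "edit distance" only has clean
semantics when the full read is spanned — so the semi-global contract is the
deliberate interpretation of combining a local-alignment kernel with an
edit-distance threshold.  The default kernel is edlib's infix mode, which
implements exactly this contract; a plain dynamic-programming kernel with
identical score semantics serves as fallback and as the oracle in the test
suite.  The score contract is exact: any kernel must agree with the DP on
the distance.  Co-optimal alignments may differ in reported coordinates
between kernels; all downstream logic depends on the span only through gene
overlap, which is insensitive to ±1 shifts at co-optimal ends.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `seed_length` | 18 | bp | long enough that random 18-mer collisions are negligible against megabase references; short enough that a 150 bp read with several mismatches retains clean seeds |
| `seed_interval` | 9 | bp | half a seed: 16 seeds per strand on a 150 bp read (tiled schedule plus an end-anchored seed) |
| `min_seed_hits` | 2 | seeds | one seed can be a chance repeat; two co-diagonal seeds rarely are |
| `diagonal_tolerance` | 5 | bp | allows small indels to keep seeds in one cluster |
| `max_edits` | 7 | edits | ≈5% of a 150 bp read; tolerates sequencing error plus strain-level divergence |
| window pad | `max_edits`+5 | bp | covers indel drift plus diagonal tolerance around the projected start |
| `max_chunk_bases` | 5×10⁷ | bp | index memory knob; any partition yields identical merged results |
| `sa_sample_rate` | 1 | — | full suffix array at desk scale; >1 trades locate speed for memory |
| `edit_slack` | 0 | edits | ambiguity resolution keeps only minimum-distance hits when enabled |
| `min_taxon_read_fraction` | 0 (off) | fraction | sample-level support filter; resolution is opt-in |
| `min_overlap` | 1 | bp | any overlap with a CDS counts; configurable |
| filter | ≥5 reads in ≥3 samples | — | low-abundance row filter applied in **each** group (conservative reading; an `any`-group mode is available) |

## Index layer

Members of a chunk are concatenated with a separator symbol outside the DNA
alphabet between records and a terminal sentinel, so matches can never span
record boundaries.  The alphabet {sentinel, separator, A, C, G, N, T} is
encoded as integers in sorted order.  N is indexed as its own symbol (an N
in the reference never matches a base) and patterns containing N are
rejected outright: ambiguous bases cannot anchor an exact seed, and the
naive oracle in the tests applies the same rule.  Coordinates are 0-based
half-open throughout the index and assignment layers; the GFF3 1-based
inclusive convention is converted exactly once, in the gene-assignment
parser.  Only the forward strand is indexed; the reverse strand is searched
by reverse-complementing the read, which halves the index.

The suffix array is built by prefix doubling (vectorized, O(n log² n)) and
kept in full by default; a sample rate > 1 stores entries at sampled text
positions and recovers the rest by LF-mapping walks.  The on-disk format is
documented in `docs/index-format.md`.

## Determinism and tie-breaks

Runs are bit-reproducible.  Candidate regions are evaluated in descending
seed support with ties broken by (taxid, accession, projected start)
ascending; a cluster's projected start is its smallest diagonal.  Chunk
merges keep, per taxon, the hit with the lowest edit distance, then the
lexicographically smallest accession, then the smallest reference start.
Gene assignment takes the maximum-overlap CDS, ties to the smallest feature
start then feature id.  When the sample-support filter would empty a read's
hit set, its minimum-edit-distance hit survives (ties to the smallest
taxid).  Fractional counting of multi-taxon reads rounds per sample column
by largest remainder, preserving column sums.

Degenerate inputs: reads shorter than one seed, or consisting of Ns, are
reported unassigned (not errors); an empty FASTQ produces a valid empty
report; an accession without annotation yields intergenic assignments with a
logged warning.

## Synthetic data

The simulator emulates the conditions the pipeline is designed for, at desk
scale:

- **Genomes** are i.i.d. random DNA at a configurable GC content with
  non-overlapping CDS features (multiples of 3, ≥150 bp) placed uniformly by
  rejection.  Independently generated genomes are ~75% divergent, far above
  the 10% separation the accuracy benchmark requires.  `diverge_genome`
  creates strains or sister species by i.i.d. substitution at a set rate
  with coordinates preserved.
- **Communities** draw log-normal relative abundances (σ = 1 by default), a
  standard skewed-abundance emulation of benchmark community profiles.
- **Reads** are 150 bp single-end, drawn from CDSs only (so gene truth is
  always defined): source species by abundance, CDS by length weighting,
  start uniform within the CDS, strand uniform.  Mutations are i.i.d.
  substitutions plus rare indel events with geometric(0.5) lengths, each
  recorded in the truth record so every read is exactly reconstructable;
  base qualities are constant because the pipeline never reads them (QC is
  upstream).

What the simulator does **not** model: realistic sequencer error profiles
(position-dependent quality, homopolymer errors), paired-end fragment-size
distributions, rRNA carryover, horizontal gene transfer, or open-world
contamination from unindexed organisms.  Passing the synthetic benchmarks
therefore demonstrates the correctness of the indexing/assignment machinery
and its behavior under divergence, not field performance on real stool or
plaque libraries.

## Validation problem sizes

The test suite runs the full pipeline at sizes chosen to exercise every code
path while remaining desk-scale: oracle-equivalence sweeps (1,000 random
patterns against a ~100 kb chunk; 500 read/window pairs against the DP
kernel; 1,000 interval queries against a linear scan), structural-invariance
checks on a five-genome community with 1,500 reads, a clean-read benchmark
(10 species × 100 kb, 50,000 error-free reads must be 100% assigned and
100% correct), and the headline benchmark (20 species × 100 kb, 50,000
reads at 0.5% substitutions, two index chunks).  `scripts/acceptance.py`
re-runs the headline benchmark end to end from a seed.

## Known limitations

- The FM-index keeps the full occurrence table in memory
  (O(text × alphabet) int64); appropriate for chunked desk-scale references,
  not for multi-gigabase databases, where a checkpointed rank structure and
  run-length BWT would be the next step.
- Ambiguity resolution is per-sample and frequency-based; no lowest-common-
  ancestor fallback or abundance re-estimation is attempted.
- Multi-gene overlaps are single-counted by maximum overlap; reads spanning
  operon boundaries contribute to one gene only (the full overlap list is
  available for auditing).
- The low-abundance filter assumes exactly two sample groups.
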