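# Methods

## Problem and model

Gene-centric single-cell pipelines drop multimapping reads, which
erases most of the signal from transposable elements (TEs): a typical
repeat subtype has hundreds to millions of near-identical genomic
copies, so a TE-derived read rarely maps uniquely. `tecount` works at
the **metagene** level: the aligner is expected to emit one best
alignment per read (e.g. STAR with `--outFilterMultimapNmax 100
--outSAMmultNmax 1`), and every genomic copy of a repeat subtype
(RepeatMasker `repName`) maps onto one counting unit. Allocation errors
among copies of the same subtype become harmless; per-copy location is
deliberately not recoverable from the output.

Reads are allocated exon-first: a read overlapping any gene exon
belongs to that gene, and only otherwise can it count toward a TE.
Three policies are exposed:

- **gene-priority** (default) — exon ⟶ gene; else TE overlap ⟶ TE;
  else unassigned. Intronic reads fall through to TEs.
- **dual** (`--mode exclusive` on the CLI, the switch's historical
  name) — the gene decision is unchanged, but a TE overlap is credited
  as a second assignment even inside exons. Gene counts are therefore
  identical between gene-priority and dual; this identity is asserted
  in the test suite.
- **nointronic** — a non-exonic read touching any gene body is
  discarded, so TE counts come only from reads fully outside gene
  bodies. This bounds the contribution of passive intronic
  co-transcription; TE totals under nointronic are a subset of the
  default's (also asserted).

Overlap semantics: any shared base makes a feature a candidate; the
blocks of a spliced read pool their overlap. Among candidates the
largest pooled overlap wins; exact ties go to the lexicographically
smallest feature name. This tie rule is a design choice (deterministic
and input-order independent); no containment requirement is imposed.
Strand is ignored — droplet 3' libraries are effectively unstranded
after alignment. MAPQ is ignored too: MAPQ-0 multimappers are the
whole point. Secondary, supplementary and unmapped records are
skipped and tallied.

## Coordinates and annotation handling

All internal coordinates are 0-based half-open. GTF (1-based inclusive)
is converted on parse; UCSC `rmsk.txt` and BED already use 0-based
starts. The gene body comes from the GTF `gene` row when present
(GENCODE always provides one) so intron semantics do not depend on
transcript completeness; without one, the union span of the exons is
used. Genes with no exon rows are skipped with a warning. In RNA mode
every RepeatMasker row is retained, including simple repeats,
low-complexity and structural-RNA classes — results for those classes
are implementation-defined rather than biologically meaningful. ATAC
mode restricts to the transposon classes {LINE, SINE, LTR, Retroposon,
DNA}, matched as substrings of `repClass` so uncertain classes such as
`DNA?` are retained, mirroring the common `grep`-based preparation of
TE BED files.

## Index

The genome overlay uses one interval tree per chromosome and category
(exons, gene bodies, TE copies), queried per block; any structure that
answers overlap queries exactly would do, and the test suite pins the
behaviour to a linear-scan reference rather than to the structure. The
serialized index is versioned JSON carrying the annotation content and
build metadata (class filter, input checksums); loading a mismatched
version fails with an instruction to rebuild. Bit-compatibility with
any other tool's index files is a non-goal.

## Deduplication and counting

With UMIs enabled, a cell-feature count is the number of distinct
(barcode, feature, UMI) triples. Including the feature in the key is a
design choice: no cross-feature UMI resolution rule is imposed, and
per-feature dedup keeps counting independent of read order. No UMI
sequence-error correction is attempted. Without UMIs, counts are kept
reads per cell-feature pair.

ATAC mode deduplicates positionally instead: at most one read per
(cell, chromosome, leftmost aligned position), first seen wins. The
scope is per cell — genome-global dedup would erase accessibility
shared across cells. Mates of a pair are deduplicated as independent
records; fragment-level dedup is a possible alternative not
implemented. An optional post-filter drops TE metagenes with fewer
than `min_te_reads` (default 1000) total counts, since very low-count
TEs are noise-dominated in sparse ATAC data; tests and small fixtures
set it to 0.

## Cell filtering

Defaults: cells with fewer than 1000 total counts **or** fewer than 500
detected features are removed, then the 10,000 surviving cells with
the most detected features are kept (ties: higher total counts, then
earlier barcode). The OR-combination is the conservative reading of
the usual "and"-phrased QC rule; a `combine="and"` switch selects the
other semantics. Ranking by detected features (not totals) follows the
"highest gene count" convention.

## Synthetic data and what it shows

The generator emulates the input boundary of the tool — post-alignment
records — not sequencing itself. A two-chromosome genome hosts genes
(2–4 exons, realistic exon/intron lengths) and TE copies in four
geometries: intergenic, intronic, inside an exon, and straddling an
exon–intron boundary. Reads (50–90 bp, single or spliced) are placed
inside a chosen source feature, with defaults of ~13% TE-derived
reads (the share reported for mouse scRNA-seq), ~10% intronic, ~12%
in a feature-free desert (guaranteed unassignable), ~2% deliberately
ambiguous placements straddling a TE edge, and a 10% PCR-duplicate
rate. Barcodes are 12-mers, UMIs 12-mers; QC traps (unmapped,
secondary, tag-less records) are injected by default.

Two constructive properties are load-bearing for the tests: TE copies
are placed pairwise more than a read length apart, so any read
overlaps at most one copy — which makes "metagene count = sum of
per-copy counts" an exact identity rather than an approximation — and
ground truth for ambiguous reads is computed by the oracle, never
hand-written.

The oracle is an index-free linear scan over every annotation interval
(vectorized per chromosome with numpy for speed) with an independent
re-implementation of the priority and tie rules; `oracle_count` is a
naive end-to-end recount including dedup. Passing these checks shows
the engine implements its stated rules exactly on data whose
generating process is known. It does not validate behaviour on real
libraries — barcode sequencing errors, soft-clipped or chimeric
alignments, strand-specific protocols and aligner idiosyncrasies are
outside the simulation.

## Problem sizes and numerics

The randomized equivalence suite uses 20 fixtures of 200 genes, 2,000
TE copies and 10⁴ reads each, checked in all three modes (~10⁵
read-level comparisons per mode overall) plus exact matrix equality;
the acceptance script re-runs five such fixtures plus a 2,000-cell
rare-population mixture (1% of cells carrying a marker-TE program,
recovered exactly by raw marker counts). All comparisons are exact
integer equality — there is no tolerance anywhere in the counting
path. Counts are int64; matrices are scipy CSR; cell rows are emitted
in sorted barcode order so output is invariant to read order and
(vacuously) to the `-p` thread flag, which is accepted for
compatibility but does not parallelize the sequential stream.

## Known limitations

No barcode whitelisting or error correction; no fragment-file input;
no GFF3; no genome/annotation auto-download; no normalization or
downstream statistics (those belong to scanpy/Seurat). A gene whose
GTF entry lacks exon rows is dropped rather than treated as a
single-exon gene. The dual mode can at most double-count a read (one
gene + one TE); consumers comparing totals across modes should use
the run report's per-category tallies.
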