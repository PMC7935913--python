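# tecount

Quantify **transposable-element (TE) expression and accessibility in
single cells**, alongside genes, from aligned single-cell RNA-seq or
ATAC-seq data.

TEs occupy close to half of a mammalian genome in hundreds to millions
of near-identical copies, so reads originating from them usually align
to many loci and are discarded by gene-centric pipelines. `tecount`
keeps those reads (one best alignment per read, including MAPQ-0
multimappers) and collapses all genomic copies of a repeat subtype
(RepeatMasker `repName`, e.g. `MERVL-int`, `IAPEz-int`, `L1MdA_I`) onto
a single **metagene**. Mis-allocation among individual copies then no
longer matters — at the price of losing per-copy genomic location. The
output is a sparse cells × (genes + TE subtypes) count matrix that
drops straight into scanpy/Seurat-style workflows.

## The counting model

For each kept alignment with reference blocks $B$ (CIGAR `N` gaps split
blocks), overlap is evaluated against three interval sets: exons $E_g$
and bodies of genes $g$, and copies of TE subtypes $t$. With
$\mathrm{ov}(B, X) = \sum_{b \in B} |b \cap X|$:

- **gene-priority** (default): assign to
  $\arg\max_g \mathrm{ov}(B, E_g)$ if any exon overlap exists, else to
  $\arg\max_t \mathrm{ov}(B, t)$ if any TE overlap exists, else
  unassigned. Intronic reads therefore fall through to TEs.
- **dual** (CLI `--mode exclusive`): the gene decision is unchanged,
  but an overlapping TE is *also* credited — a read from a TE inside an
  exon/UTR counts for both.
- **nointronic**: exonic reads go to genes; any other read touching a
  gene body is discarded; only reads fully outside gene bodies can
  count toward TEs. This isolates TE signal from passive intronic
  co-transcription.

Ties are broken by the larger pooled overlap, then lexicographically.
Cell demultiplexing uses `CR:Z` tags, file names (one file per cell,
C1/SMART-seq style, `-CB False`), or the read-name prefix (10x ATAC
preprocessing). Counts are distinct (barcode, feature, UMI) triples
when UMIs (`UR:Z`) are enabled, read counts otherwise. ATAC mode uses a
TE-only index restricted to the LINE/SINE/LTR/Retroposon/DNA classes
and deduplicates positionally: one read per (cell, chromosome, start).

## Worked example

```python
from tecount import (build_index, quantify, CountMode, AssignmentMode,
                     parse_gtf, parse_rmsk)
from tecount.synthetic import FixtureSpec, make_annotation, simulate_reads

spec = FixtureSpec(n_genes=50, n_te_subtypes=20, copies_per_subtype=10,
                   n_cells=20, reads_per_cell=100, seed=0)
ann = make_annotation(spec)                # genes + TE copies, known layout
simulate_reads(spec, ann, "reads.sam")     # tagged SAM with ground truth
index = build_index(ann.genes, ann.tes)
matrix, report = quantify(["reads.sam"], index, CountMode(AssignmentMode.GENE_PRIORITY))
print(matrix)                  # CountMatrix(20 cells x 70 features)
print(report.qc["kept"], report.assigned)
```

prints

```
CountMatrix(20 cells x 70 features)
2000 {'GENE': 1313, 'TE': 274, 'UNASSIGNED': 413}
```

i.e. all 2000 simulated reads were kept, ~66% landed in gene exons,
~14% in TE metagenes (about the share seen in real mouse scRNA-seq
data), and the remainder — reads from the feature-free region plus
intronic reads with no TE beneath them — stayed unassigned. The 70
columns are 50 gene names followed by 20 TE subtypes.

The same flow from the shell:

```sh
tecount build --gtf genes.gtf --te rmsk.txt -o genome.idx
tecount count -i reads.sam -x genome.idx -o run --mode exclusive \
       --expect-cells 10000 --min_count 1000 --min_genes 500
tecount atac-build --te mm10.te.bed -o te.atac.idx
tecount atac-count -i atac.sam -x te.atac.idx -CB True -UMI False -o atac_run
```

Each counting run writes the matrix (CSV or MatrixMarket + sidecars)
and a JSON run report with read/QC tallies and the parameters used.

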