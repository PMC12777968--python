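# pileview

Portable, self-contained read-pileup reports from the command line.

Visual inspection of aligned sequencing reads ("pileups") is routine in
variant review and QC, but the usual viewers either need a graphical
desktop (hard to run on a cluster), or a server component (hard to share).
`pileview` generates IGV-style pileup visualizations of a genomic region
directly from SAM/BAM/CRAM + FASTA, entirely headless, and writes them as:

- a **single self-contained HTML file** — data and rendering logic embedded,
  opens in any browser with no server or network access, small enough to
  email;
- **static images** (SVG, PNG, PDF);
- the **underlying data** (JSON, TSV) for embedding in downstream reports.

The interactive report supports read-name search/filtering and hover
tooltips, and encodes mapping quality in the read border color: confident
placements (MAPQ ≥ 60) are grey, uncertain ones fade through yellow to
vermillion at MAPQ 0.  All colors come from Wong's colorblind-safe palette.

## How it stays small

Two ideas keep reports compact and layouts tight:

**Edit-track encoding.** Instead of embedding read sequences, each
alignment is stored as a pipe-delimited string of its differences from the
reference — e.g. `50=|3d|10=|1C|1G|iGGT` is 50 matching bases, a 3 bp
deletion, 10 matches, a C and a G mismatch, and an inserted GGT.  All
per-read metadata (`name pos mapq strand edits`) is concatenated into one
flat string with the sentinel `§` between records (a character the SAM
QNAME alphabet cannot contain), lz-string-compressed, and decoded
client-side.  The report's mark/transform structure is constant-size;
only this payload grows with read count.

**Optimal row packing.** Fragments (a read, or a mate pair spanning
`[leftmost, rightmost]` aligned base) must be stacked so that no two
overlapping fragments share a row, using as few rows *r* as possible:
find ρ : F → {1..r} with ρ(f) ≠ ρ(f′) whenever I_f ∩ I_f′ ≠ ∅.  The
conflict graph of intervals is an interval graph, where greedy first-fit
coloring in order of left endpoint is exactly optimal: *r* equals the
clique number ω — the maximum number of fragments over any single base —
and the assignment runs in near-linear time.

## Worked example

Build a small synthetic dataset (bundled generator, fully seeded) and plot
a 1000 bp window:

```python
from pathlib import Path
from pileview.fixtures import make_reference, make_reads, ReadProfile

out = Path("demo"); out.mkdir(exist_ok=True)
seq = make_reference(3000, seed=11, out_path=out / "ref.fa")
make_reads(seq, 100, ReadProfile(read_length=100, mismatch_rate=0.01),
           seed=12, out_path=out / "reads.bam")
```

```console
$ pileview --bam reads.bam --reference ref.fa --around ref:1500 \
           --output pileup.html --verbose
reading reads.bam over ref:1000-1999
40 reads in 23 fragments on 8 rows
wrote pileup.html
```

40 reads intersect the window `ref:1000-1999` (a 1000 bp window centered
on position 1500); mate pairs collapse them to 23 fragments, which pack
into 8 display rows — the maximum read depth over any base in the window.
`pileup.html` (~39 kB) opens directly in a browser: coverage and reference
on top, one fragment per row, mismatches colored by nucleotide, mates
joined by thin linkers, and a search box to highlight reads by name.

The same data as a table:

```console
$ pileview --bam reads.bam --reference ref.fa --region ref:1400-1600 --format tsv | head -6
#reads
name	pos	mapq	strand	row	edits
read00012	1304	60	-	1	41=|1A|24=|1A|9=|1T|23=
read00030	1318	60	+	2	50=|1C|49=
read00030	1507	60	-	2	100=
read00025	1339	60	-	3	96=|1T|3=
```

Each row is one read: `read00030`'s two mates share row 2, and its first
mate carries a single C mismatch after 50 matching bases.

Run `pileview` with no arguments on a terminal to get an interactive
wizard that detects alignment/reference files in the working directory and
builds the same command step by step.  Highlights can be layered from
explicit spans (`--highlight LABEL:START-END`), variant sites (`--vcf`),
or intervals (`--bed`).

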