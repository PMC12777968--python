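# Methods

This note documents the models, encodings, and design choices behind
`pileview`, and what the test suite does and does not establish.

## Coordinates and region parsing

All user-facing coordinates are 1-based inclusive (`17:7661779-7687546`,
samtools convention); internal arrays are 0-based half-open.  The span
separator may be an ASCII hyphen or an en-dash (papers and clinical
reports often print the latter), and coordinates may contain
thousands-commas.  `--around CHROM:POS` builds a window of total width
`--window` (default 1000 bp, the conventional per-variant review window)
with `start = max(1, pos − window/2)`; the window is centered except when
clamped at the chromosome start, where width is preserved instead.  The
leading token of a `--highlight` argument is always a free-form label —
it is deliberately never validated against the reference, so gene symbols
work as labels.

## Edit-track encoding

Each alignment is re-encoded relative to the reference with the grammar

```
track := token ("|" token)*
token := INT "="           match run
       | INT BASE          mismatch run (identical read bases)
       | INT "d"           deletion
       | INT "n"           splice skip (CIGAR N)
       | "i" SEQ           insertion (consumes no reference bases)
```

CIGAR M runs are split by base comparison against the reference; `=`/`X`
ops are also re-verified so the encoder never trusts a claimed match.
Choices worth recording:

- **Mismatch tokens store the read base** (what gets drawn and colored),
  not the reference base.
- **Adjacent identical mismatch bases merge** into one token; differing
  bases stay separate tokens.  Adjacent match runs always merge.  The
  output is therefore minimal under the grammar.
- **Soft/hard clips and padding are dropped entirely**; a fragment's
  interval counts aligned bases only.
- **Splice skips get their own token** (`n`), drawn as a thin connector —
  an extension beyond DNA-only viewers, useful for RNA alignments.
- Insertions attach to the boundary between flanking reference positions
  and consume no reference span.

At a 1% edit rate the edit strings total ~11–13% of the raw read bases;
each mismatch costs ~8 characters of tokens, so the representation stays
below 20% of the raw sequence up to ~2.5% edit density and degrades
gracefully beyond.

## Packing and compression

Per-read records are `name pos mapq strand edits`, space-delimited,
joined with the sentinel `§` (U+00A7).  SAM QNAMEs are printable ASCII
excluding space, so neither delimiter can occur in a name; this is still
asserted defensively at pack time.  Strand is carried beyond the minimal
position/MAPQ/identifier triple because rendering read orientation
requires it.  Auxiliary tags requested with `--aux-tag` travel in a JSON
side table keyed by read name rather than in the packed string — they are
tooltip-only and often absent.

The serialized plot spec is compressed with an in-package implementation
of the lz-string scheme (UTF-16-safe dialect): an LZW-family dictionary
coder packing 15 bits per UTF-16 code unit, offset by +32 so all output
characters are printable, surrogate-free BMP text.  Compression and
decompression are independent transliterations of the published
algorithm; the HTML report ships a third, JavaScript transliteration of
the decompressor.  Roundtrip identity is property-tested over arbitrary
unicode (including astral characters, which are processed as UTF-16 code
units to match JavaScript string semantics).  When embedding, the
compressed string is additionally `\uXXXX`-escaped, so report files are
pure ASCII and immune to transport encoding issues.

## Row assignment

Fragments are intervals `I_f` from the leftmost to the rightmost aligned
base of their member reads — for mate pairs this includes the unsequenced
insert, so nothing is ever drawn between mates on their row.  Greedy
first-fit over fragments sorted by `(start, end, name)` assigns each
fragment the smallest free row; on interval graphs this is exactly
optimal, with the row count equal to the maximum point depth.  The sort
key makes layouts reproducible; permuting the input can change which
fragment gets which row but never the row count (property-tested, and
verified against exhaustive-search chromatic numbers on small instances).

## Subsampling, coverage

Subsampling (`--max-read-depth`, default 500) draws a uniform random
subset of *fragments* — whole mate pairs, never splitting a pair — using
`random.Random(seed)` with the run's fixed seed (default 42), so repeated
runs select identical fragments.  Coverage counts aligned (match or
mismatch) bases only; deletions, splice skips, and pair gaps do not
count, matching the usual pileup-depth convention.  Duplicates and
QC-fail reads are kept (only unmapped/secondary/supplementary records are
filtered); a pileup viewer should show what the caller saw.

## Visual encoding

Colors are Wong's colorblind-safe palette throughout: A green `#009E73`,
C blue `#0072B2`, G orange `#E69F00`, T vermillion `#D55E00`, N/match
grey `#999999`.  Read borders encode MAPQ by piecewise-linear RGB
interpolation anchored at 0 → vermillion, 30 → yellow `#F0E442`, 60 →
grey, clamped above 60.  The 60 endpoint is the conventional
"near-certain" threshold; 30 (≈1/1000 placement error) is this package's
choice of midpoint for the fade.  Reverse-strand reads get a small
pointed end (can be disabled via `PlotOptions(show_arrows=False)`).
Reference letters render only when the window is ≤ 2000 bp *and* at least
4 px/base — beyond that they cannot be legible; coverage bars always
render.

## Plot specification and report

The declarative spec targets the Vega-Lite v5 JSON grammar (`$schema`
pinned in the output): three vertically concatenated tracks (coverage,
reference, reads-with-highlights), a `read_search` text parameter, and a
constant-size transform pipeline that splits the single packed payload on
`§`/spaces/`|` at render time.  Conformance is asserted structurally in
the tests (top-level shape, mark/encoding presence, dataset tables,
palette membership); the spec is additionally carried verbatim in JSON
exports for downstream embedding.

The embedded HTML report inlines the package's own client runtime — the
lz-string decompressor plus an SVG pileup renderer with read-name search
and tooltips — so an embedded report contains zero external references
and opens offline.  `--no-embed-js` instead references version-pinned
Vega CDN URLs and inlines only the decompressor and an embed shim,
yielding a smaller file that needs network access, and delegates
rendering to the Vega-Lite runtime.

Static SVG is drawn server-side from the fully expanded marks
(deterministic text output, byte-identical across runs); PNG and PDF
paint the same mark list with matplotlib, with file metadata
(timestamps, producer) suppressed.  No output format embeds a timestamp
or hostname: `(inputs, flags, seed)` fully determine all bytes written.

## Synthetic data generator

`pileview.fixtures` emulates a well-behaved short-read library: uniform
random reference; reads placed uniformly; per-base mismatch (default 1%)
and indel (default 0.1%, lengths 1–3) processes; fully paired by default
with Gaussian insert sizes (300 ± 30 bp); MAPQ drawn from a mixture
dominated by 60 with a tail of uncertain placements.  Every read's true
position, CIGAR, and expected edit string go into a manifest, so the
whole pipeline (writer → BAM on disk → reader → encoder) is checked
end-to-end against ground truth.  Files are written through pysam's
writers, never hand-assembled.

What the generator does **not** emulate: quality-dependent error
profiles, chimeric/split reads, coverage biases, multi-chromosome
references, real read names.  Passing tests therefore demonstrate
correctness of parsing, encoding, layout, and export on well-formed
input — not robustness to pathological real-world BAMs.

Default problem sizes in the tests and the acceptance script (references
of 2–3 kb, libraries of 100–1000 reads, 100–200 random layout instances,
1000 random codec triples) were chosen as the smallest sizes at which
every mechanism — pairing, subsampling, multi-row packing, payload
compression — is genuinely exercised.

## Numerical / degenerate-input choices

- Closed intervals: fragments touching at a single base conflict.
- Empty read list → valid dataset, empty payload, spec and exports with
  reference/coverage only.
- Zero-coverage windows render with an all-zero coverage track.
- Symbolic VCF ALTs (`<DEL>`, `*`) fall back to a single-base highlight
  at POS, since the REF-length rule has no meaning for them.
- More than two primary alignments sharing a QNAME is rejected as corrupt
  input rather than silently mis-paired.
- Reads extending beyond the window are kept whole and clipped at render
  time.

## Known limitations

- The interactive renderer and the Vega-Lite spec are two projections of
  the same dataset; visual parity between them (and with the static SVG)
  is structural, not pixel-exact.
- CRAM requires the reference FASTA (passed through to htslib).
- Chromosome-name aliasing (`chr1` vs `1`) is not attempted.
- Plain SAM inputs are scanned sequentially (no index), which is fine for
  the file sizes SAM is used for.
- Base-quality shading and multi-sample/multi-region layouts are out of
  scope.
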