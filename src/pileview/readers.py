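"""Ingest alignments, reference sequence, and highlight sources.

All standard formats go through pysam/htslib: SAM/BAM/CRAM (+BAI/CRAI),
FASTA (+FAI), VCF/BCF.  BED (3–6 column, tab-delimited) is read directly so
that malformed lines can be reported with their line number.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence, Tuple

import pysam

from .core import AlignedRead, GenomicRegion, Highlight
from .encoding import encode_edits


def _ref_span(cigartuples) -> int:
    # M/D/N/=/X consume reference
    return sum(length for op, length in cigartuples if op in (0, 2, 3, 7, 8))


def read_alignments(
    alignment_path: os.PathLike,
    region: GenomicRegion,
    aux_tags: Sequence[str] = (),
    *,
    fasta_path: Optional[os.PathLike] = None,
) -> List[AlignedRead]:
    """All primary mapped reads whose aligned span intersects ``region``.

    Unmapped, secondary, and supplementary records are excluded; duplicates
    and QC-fail reads are kept.  Reads extending beyond the window are kept
    whole (they are clipped at render time).  Each read carries the
    requested ``aux_tags`` that are present on its record, and its edit
    track relative to the reference.

    ``fasta_path`` supplies the reference needed to split CIGAR M runs into
    matches and mismatches; it may be omitted only for alignments whose
    CIGARs use explicit =/X ops.  Indexed BAM/CRAM files are fetched by
    region; plain SAM is scanned sequentially.
    """
    if not os.path.exists(alignment_path):
        raise FileNotFoundError(f"alignment file not found: {alignment_path}")
    mode_kwargs = {}
    if fasta_path is not None:
        mode_kwargs["reference_filename"] = str(fasta_path)  # CRAM decoding
    fasta = pysam.FastaFile(str(fasta_path)) if fasta_path is not None else None
    try:
        with pysam.AlignmentFile(str(alignment_path), **mode_kwargs) as af:
            if region.chrom not in af.references:
                raise ValueError(
                    f"chromosome {region.chrom!r} not in {alignment_path} header "
                    f"(has: {', '.join(af.references[:5])}{'...' if af.nreferences > 5 else ''})"
                )
            try:
                records = af.fetch(region.chrom, region.start - 1, region.end)
            except ValueError:
                # no index (e.g. plain SAM): scan and filter
                records = (
                    rec
                    for rec in af.fetch(until_eof=True)
                    if rec.reference_name == region.chrom
                    and not rec.is_unmapped
                    and rec.reference_start < region.end
                    and rec.reference_end is not None
                    and rec.reference_end > region.start - 1
                )
            reads = []
            for rec in records:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.cigartuples is None or rec.query_sequence is None:
                    continue
                pos = rec.reference_start + 1
                span = _ref_span(rec.cigartuples)
                if span == 0:
                    continue
                if fasta is not None:
                    ref_slice = fasta.fetch(
                        region.chrom, rec.reference_start, rec.reference_start + span
                    )
                else:
                    ref_slice = _ref_slice_from_record(rec, span)
                aux = tuple(
                    (tag, str(rec.get_tag(tag)))
                    for tag in aux_tags
                    if rec.has_tag(tag)
                )
                mate_pos = None
                if (
                    rec.is_paired
                    and not rec.mate_is_unmapped
                    and rec.next_reference_name == rec.reference_name
                ):
                    mate_pos = rec.next_reference_start + 1
                reads.append(
                    AlignedRead(
                        name=rec.query_name,
                        pos=pos,
                        mapq=rec.mapping_quality,
                        strand="-" if rec.is_reverse else "+",
                        edits=encode_edits(rec.query_sequence, rec.cigartuples, ref_slice),
                        is_paired=rec.is_paired,
                        mate_pos=mate_pos,
                        aux=aux,
                    )
                )
    finally:
        if fasta is not None:
            fasta.close()
    reads.sort(key=lambda r: (r.pos, r.name))
    return reads


def _ref_slice_from_record(rec, span: int) -> str:
    """Reconstruct the reference slice from explicit =/X CIGARs (no FASTA given).

    Mismatched reference bases are unknowable without the FASTA, so X
    positions are filled with a base guaranteed to differ from the read
    base; M ops are rejected.
    """
    out = []
    qpos = 0
    for op, length in rec.cigartuples:
        if op == 0:
            raise ValueError(
                "CIGAR M ops require a reference FASTA to classify matches/mismatches"
            )
        if op == 7:  # =
            out.append(rec.query_sequence[qpos : qpos + length].upper())
            qpos += length
        elif op == 8:  # X
            for qb in rec.query_sequence[qpos : qpos + length].upper():
                out.append("A" if qb != "A" else "C")
            qpos += length
        elif op in (2, 3):  # D/N — reference bases never compared
            out.append("N" * length)
        elif op in (1, 4):
            qpos += length
    return "".join(out)


def fetch_reference(fasta_path: os.PathLike, region: GenomicRegion) -> str:
    """Uppercase reference bases over the region (exactly ``len(region)``)."""
    with pysam.FastaFile(str(fasta_path)) as fasta:
        if region.chrom not in fasta.references:
            raise ValueError(f"chromosome {region.chrom!r} not in {fasta_path}")
        length = fasta.get_reference_length(region.chrom)
        if region.end > length:
            raise ValueError(
                f"region {region} exceeds chromosome length {length}"
            )
        return fasta.fetch(region.chrom, region.start - 1, region.end).upper()


def highlights_from_vcf(vcf_path: os.PathLike, region: GenomicRegion) -> List[Highlight]:
    """One highlight per variant record intersecting the region.

    The span is POS..POS+len(REF)−1 (so deletions shade their full deleted
    stretch); symbolic ALTs (``<DEL>`` etc.) fall back to a single base at
    POS.  Labels use the record ID when set, else ``REF>ALT``.
    """
    highlights = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.chrom != region.chrom:
                continue
            start = rec.pos  # pysam: 1-based
            alts = rec.alts or ()
            symbolic = any(a.startswith("<") or a == "*" for a in alts)
            end = start if symbolic else start + len(rec.ref) - 1
            if not region.overlaps(start, end):
                continue
            if rec.id:
                label = rec.id
            else:
                label = f"{rec.ref}>{','.join(alts) if alts else '.'}"
            highlights.append(
                Highlight(
                    region=GenomicRegion(region.chrom, start, end),
                    label=label,
                    source="vcf",
                )
            )
    return highlights


def highlights_from_bed(bed_path: os.PathLike, region: GenomicRegion) -> List[Highlight]:
    """Intersecting BED intervals as highlights.

    BED's 0-based half-open coordinates become 1-based inclusive; column 4
    (when present) supplies the label.
    """
    highlights = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{bed_path}:{lineno}: expected >= 3 tab-delimited columns"
                )
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{bed_path}:{lineno}: non-numeric coordinates "
                    f"{fields[1]!r}/{fields[2]!r}"
                ) from None
            if end0 <= start0:
                raise ValueError(f"{bed_path}:{lineno}: empty or inverted interval")
            start, end = start0 + 1, end0
            if chrom != region.chrom or not region.overlaps(start, end):
                continue
            label = fields[3] if len(fields) >= 4 else ""
            highlights.append(
                Highlight(
                    region=GenomicRegion(chrom, start, end), label=label, source="bed"
                )
            )
    return highlights
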