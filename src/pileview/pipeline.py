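"""End-to-end assembly: files in, :class:`PlotDataset` out.

The pipeline is: read alignments → assemble fragments → subsample →
assign rows → compute coverage → pack payload.  Exporters then turn the
dataset into HTML/SVG/PNG/PDF/JSON/TSV.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence

from .core import GenomicRegion, Highlight, PlotDataset
from .encoding import pack_reads
from .layout import assemble_fragments, assign_rows, compute_coverage, subsample_fragments
from .plotspec import PlotOptions
from .readers import (
    fetch_reference,
    highlights_from_bed,
    highlights_from_vcf,
    read_alignments,
)


def build_dataset(
    alignment_path: os.PathLike,
    fasta_path: os.PathLike,
    region: GenomicRegion,
    options: Optional[PlotOptions] = None,
    highlights: Sequence[Highlight] = (),
    vcf_path: Optional[os.PathLike] = None,
    bed_path: Optional[os.PathLike] = None,
) -> PlotDataset:
    """Run the full pipeline for one region.

    ``highlights`` are explicit ones; VCF/BED sources are merged in when
    given (explicit first, then VCF, then BED — all shown identically).
    """
    options = options or PlotOptions()
    reference = fetch_reference(fasta_path, region)
    reads = read_alignments(
        alignment_path, region, aux_tags=options.aux_tags, fasta_path=fasta_path
    )
    fragments = assemble_fragments(reads, region)
    fragments = subsample_fragments(
        fragments, max_depth=options.max_read_depth, seed=options.seed,
        plot_all=options.plot_all,
    )
    assignment = assign_rows(fragments)
    kept_reads = [r for f in fragments for r in f.reads]
    coverage = compute_coverage(kept_reads, region)

    all_highlights: List[Highlight] = list(highlights)
    if vcf_path is not None:
        all_highlights.extend(highlights_from_vcf(vcf_path, region))
    if bed_path is not None:
        all_highlights.extend(highlights_from_bed(bed_path, region))

    return PlotDataset(
        region=region,
        reference=reference,
        coverage=coverage,
        fragments=fragments,
        highlights=all_highlights,
        packed_values=pack_reads(kept_reads).payload,
        n_rows=assignment.r,
    )
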