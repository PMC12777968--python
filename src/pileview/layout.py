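"""Fragment assembly, subsampling, row packing, and coverage.

Row packing is the pileup's one combinatorial problem: assign each fragment
f (with chromosome interval I_f) a row ρ(f) ∈ {1..r} such that no two
overlapping fragments share a row and r is minimal.  The conflict graph —
vertices = fragments, edges between fragments whose intervals intersect —
is an interval graph, where greedy first-fit coloring in order of left
endpoint is exactly optimal: the number of rows used equals the clique
number ω(G), i.e. the maximum number of fragments stacked over any single
base.  No search is needed and the assignment runs in near-linear time.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .core import AlignedRead, Fragment, GenomicRegion
from .encoding import decode_edits


def assemble_fragments(reads: Sequence[AlignedRead], region: GenomicRegion) -> List[Fragment]:
    """Group mate pairs into two-read fragments; everything else is a singleton.

    Two reads pair up iff they share a name (both must already intersect the
    region — the reader only yields such reads).  A mate outside the window
    or on another chromosome simply never shows up, leaving a singleton.
    More than two primary reads with one name means corrupt input.
    """
    by_name: Dict[str, List[AlignedRead]] = {}
    order: List[str] = []
    for read in reads:
        if read.name not in by_name:
            order.append(read.name)
        by_name.setdefault(read.name, []).append(read)

    fragments = []
    for name in order:
        group = by_name[name]
        if len(group) > 2:
            raise ValueError(
                f"{len(group)} primary alignments share the name {name!r}; "
                "input is corrupt (secondary/supplementary records should be filtered)"
            )
        fragments.append(Fragment(reads=tuple(group)))
    fragments.sort(key=lambda f: (f.start, f.name))
    return fragments


def subsample_fragments(
    fragments: Sequence[Fragment],
    max_depth: int = 500,
    seed: int = 42,
    plot_all: bool = False,
) -> List[Fragment]:
    """Uniform random subset of ``max_depth`` fragments, reproducible per seed.

    Whole fragments are the sampling unit so mates are never separated.
    Identity when ``plot_all`` is set or the input already fits.  Output
    keeps (start, name) order.
    """
    if max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    fragments = sorted(fragments, key=lambda f: (f.start, f.name))
    if plot_all or len(fragments) <= max_depth:
        return list(fragments)
    rng = random.Random(seed)
    keep = sorted(rng.sample(range(len(fragments)), max_depth))
    return [fragments[i] for i in keep]


@dataclass(frozen=True)
class RowAssignment:
    """ρ as a mapping from fragment index (input order) to row, plus the row count."""

    rows: Dict[int, int]
    r: int


def assign_rows(fragments: Sequence[Fragment]) -> RowAssignment:
    """Greedy first-fit coloring of the fragment interval graph.

    Fragments are processed by (start, end, name); each takes the smallest
    row whose previous occupant ends before it starts.  Sorted by left
    endpoint, first-fit is optimal on interval graphs, so ``r`` equals the
    maximum point overlap.  Fragment ``row`` attributes are set in place
    (1-based).
    """
    indexed = sorted(
        range(len(fragments)),
        key=lambda i: (fragments[i].start, fragments[i].end, fragments[i].name),
    )
    row_last_end: List[int] = []  # row i (0-based) → last occupied end coordinate
    rows: Dict[int, int] = {}
    for i in indexed:
        frag = fragments[i]
        for row, last_end in enumerate(row_last_end):
            if last_end < frag.start:  # closed intervals: touching bases conflict
                row_last_end[row] = frag.end
                rows[i] = row + 1
                break
        else:
            row_last_end.append(frag.end)
            rows[i] = len(row_last_end)
        frag.row = rows[i]
    return RowAssignment(rows=rows, r=len(row_last_end))


def compute_coverage(reads: Sequence[AlignedRead], region: GenomicRegion) -> np.ndarray:
    """Per-base depth over the region: aligned (match or mismatch) bases only.

    Deletions, splice skips, and the unsequenced gap between mates do not
    count, matching the usual pileup-depth convention.
    """
    n = len(region)
    diff = np.zeros(n + 1, dtype=np.int64)
    for read in reads:
        for el in decode_edits(read.edits.text, read.pos):
            if el.kind not in ("match", "mismatch"):
                continue
            lo = max(el.start, region.start) - region.start
            hi = min(el.end, region.end) - region.start + 1
            if lo < hi:
                diff[lo] += 1
                diff[hi] -= 1
    return np.cumsum(diff[:-1])
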