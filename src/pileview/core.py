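"""Domain types and region/highlight string parsing.

Coordinates are 1-based inclusive everywhere a user sees them (the samtools
convention, e.g. ``17:7661779-7687546``); internal arrays are 0-based
half-open.  The types here are shared by every other module: a
:class:`GenomicRegion` is the window being plotted, an :class:`AlignedRead`
is one alignment record reduced to what the plot needs, a :class:`Fragment`
is the display unit (one read or a mate pair), and a :class:`PlotDataset`
bundles everything an exporter consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Tuple, Union


class ParseError(ValueError):
    """A region/highlight/edit-string could not be parsed."""


# --------------------------------------------------------------------------
# Regions and highlights
# --------------------------------------------------------------------------

# span separator: ASCII hyphen or typographic en-dash (papers print the latter)
_SEP = re.compile(r"[-–]")


@dataclass(frozen=True)
class GenomicRegion:
    """A chromosome plus an inclusive 1-based coordinate span."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom or re.search(r"\s", self.chrom):
            raise ParseError(f"invalid chromosome name: {self.chrom!r}")
        if not (1 <= self.start <= self.end):
            raise ParseError(
                f"invalid span {self.start}-{self.end}: need 1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        """Closed-interval overlap with ``[start, end]`` on the same chromosome."""
        return start <= self.end and end >= self.start


@dataclass(frozen=True)
class Highlight:
    """A background-shaded span with a display label.

    ``source`` records where the highlight came from: an explicit
    ``LABEL:START-END`` argument, a VCF/BCF record, or a BED interval.
    """

    region: GenomicRegion
    label: str = ""
    source: Literal["explicit", "vcf", "bed"] = "explicit"


def _parse_coord(token: str) -> int:
    """One coordinate; thousands-commas are tolerated (``7,661,779``)."""
    cleaned = token.replace(",", "")
    if not cleaned.isdigit():
        raise ParseError(f"non-numeric coordinate: {token!r}")
    return int(cleaned)


def _parse_span(chrom: str, span: str, spec: str) -> GenomicRegion:
    parts = _SEP.split(span)
    if len(parts) != 2:
        raise ParseError(f"malformed span {span!r} in {spec!r}: expected START-END")
    start, end = (_parse_coord(p) for p in parts)
    if start > end:
        raise ParseError(f"start > end in {spec!r} ({start} > {end})")
    if start < 1:
        raise ParseError(f"coordinates are 1-based; got start={start} in {spec!r}")
    return GenomicRegion(chrom, start, end)


def parse_region(spec: str) -> GenomicRegion:
    """Parse ``CHROM:START-END`` into a :class:`GenomicRegion`.

    The separator may be an ASCII hyphen or an en-dash, and coordinates may
    contain thousands-commas.  The chromosome name (everything before the
    final colon) is preserved verbatim.

    >>> parse_region("17:7661779-7687546")
    GenomicRegion(chrom='17', start=7661779, end=7687546)
    """
    chrom, sep, span = spec.strip().rpartition(":")
    if not sep or not chrom:
        raise ParseError(f"malformed region {spec!r}: expected CHROM:START-END")
    return _parse_span(chrom, span, spec)


def parse_highlight(spec: str) -> Highlight:
    """Parse ``LABEL:START-END`` into an explicit :class:`Highlight`.

    The leading token is always treated as a free-form label (it is never
    validated against the reference), so both ``BRCA1:41196311-41277500``
    and a bare chromosome name work.
    """
    region = parse_region(spec)
    return Highlight(region=region, label=region.chrom, source="explicit")


def region_around(chrom: str, pos: int, window: int = 1000) -> GenomicRegion:
    """A window of total width ``window`` centered on ``pos``.

    ``start = max(1, pos - window // 2)`` and the width is preserved, so the
    window is only asymmetric when clamped at the chromosome start.  The
    default width of 1000 bp is the conventional per-variant review window.
    """
    if pos < 1:
        raise ParseError(f"position must be >= 1, got {pos}")
    if window < 1:
        raise ParseError(f"window must be >= 1, got {window}")
    start = max(1, pos - window // 2)
    return GenomicRegion(chrom, start, start + window - 1)


# --------------------------------------------------------------------------
# Edit tracks
# --------------------------------------------------------------------------

_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class Match:
    length: int


@dataclass(frozen=True)
class Mismatch:
    """``length`` consecutive read bases, all ``base``, differing from the reference."""

    length: int
    base: str


@dataclass(frozen=True)
class Deletion:
    length: int


@dataclass(frozen=True)
class Skip:
    """An RNA splice gap (CIGAR N); drawn as a thin connector."""

    length: int


@dataclass(frozen=True)
class Insertion:
    sequence: str


EditOp = Union[Match, Mismatch, Deletion, Skip, Insertion]

_TOKEN = re.compile(r"^(?:(\d+)(=|d|n|[ACGTN])|i([ACGTN]+))$")


def _ref_consumed(op: EditOp) -> int:
    if isinstance(op, Insertion):
        return 0
    return op.length


@dataclass(frozen=True)
class EditTrack:
    """A read's pipe-delimited edit string relative to the reference.

    Only differences from the reference are stored — e.g.
    ``50=|3d|10=|1C|1G|iGGT`` is 50 matching bases, a 3 bp deletion, 10
    matches, a C and a G mismatch, and a trailing GGT insertion.  Grammar::

        track := token ("|" token)*
        token := INT "="          match run
               | INT "d"          deletion
               | INT "n"          splice skip
               | INT BASE         mismatch run of identical read bases
               | "i" SEQ          insertion (consumes no reference bases)
    """

    ops: Tuple[EditOp, ...]

    def __post_init__(self) -> None:
        for op in self.ops:
            if isinstance(op, Insertion):
                if not op.sequence or set(op.sequence) - _BASES:
                    raise ParseError(f"invalid insertion sequence {op.sequence!r}")
            else:
                if op.length < 1:
                    raise ParseError(f"edit op length must be >= 1: {op}")
                if isinstance(op, Mismatch) and op.base not in _BASES:
                    raise ParseError(f"invalid mismatch base {op.base!r}")

    @property
    def ref_span(self) -> int:
        """Reference bases consumed (insertions consume none)."""
        return sum(_ref_consumed(op) for op in self.ops)

    @property
    def text(self) -> str:
        """Canonical pipe-delimited rendering."""
        parts = []
        for op in self.ops:
            if isinstance(op, Match):
                parts.append(f"{op.length}=")
            elif isinstance(op, Mismatch):
                parts.append(f"{op.length}{op.base}")
            elif isinstance(op, Deletion):
                parts.append(f"{op.length}d")
            elif isinstance(op, Skip):
                parts.append(f"{op.length}n")
            else:
                parts.append(f"i{op.sequence}")
        return "|".join(parts)

    @classmethod
    def parse(cls, text: str) -> "EditTrack":
        """Inverse of :attr:`text`; raises :class:`ParseError` with the token index."""
        if text == "":
            return cls(ops=())
        ops: list[EditOp] = []
        for i, token in enumerate(text.split("|")):
            m = _TOKEN.match(token)
            if not m:
                raise ParseError(f"bad edit token {token!r} at index {i}")
            if m.group(3) is not None:
                ops.append(Insertion(m.group(3)))
                continue
            length, kind = int(m.group(1)), m.group(2)
            if kind == "=":
                ops.append(Match(length))
            elif kind == "d":
                ops.append(Deletion(length))
            elif kind == "n":
                ops.append(Skip(length))
            else:
                ops.append(Mismatch(length, kind))
        return cls(ops=tuple(ops))


# --------------------------------------------------------------------------
# Reads, fragments, datasets
# --------------------------------------------------------------------------

# SAM QNAMEs are printable ASCII excluding space — the packing sentinel `§`
# (U+00A7) therefore can never occur in a name.
_QNAME_OK = re.compile(r"^[!-~]+$")


@dataclass(frozen=True)
class AlignedRead:
    """One alignment record reduced to what the pileup needs."""

    name: str
    pos: int  # 1-based leftmost aligned reference position
    mapq: int
    strand: Literal["+", "-"]
    edits: EditTrack
    is_paired: bool = False
    mate_pos: Optional[int] = None
    aux: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not _QNAME_OK.match(self.name):
            raise ParseError(f"invalid read name {self.name!r}")
        if not (0 <= self.mapq <= 255):
            raise ParseError(f"MAPQ out of range: {self.mapq}")
        if self.strand not in ("+", "-"):
            raise ParseError(f"invalid strand {self.strand!r}")

    @property
    def end(self) -> int:
        """1-based rightmost aligned reference position."""
        return self.pos + self.edits.ref_span - 1


@dataclass
class Fragment:
    """One or two mated reads laid out as a single interval.

    The interval runs from the leftmost aligned base of any member read to
    the rightmost, so for a mate pair it includes the unsequenced insert —
    the thin linker occupies the row too.
    """

    reads: Tuple[AlignedRead, ...]
    row: int = 0  # display row, assigned by layout (1-based; 0 = unassigned)

    def __post_init__(self) -> None:
        if not 1 <= len(self.reads) <= 2:
            raise ValueError("a fragment holds one or two reads")
        if len(self.reads) == 2 and self.reads[0].name != self.reads[1].name:
            raise ValueError("mate reads must share a name")
        self.reads = tuple(sorted(self.reads, key=lambda r: r.pos))

    @property
    def name(self) -> str:
        return self.reads[0].name

    @property
    def start(self) -> int:
        return min(r.pos for r in self.reads)

    @property
    def end(self) -> int:
        return max(r.end for r in self.reads)

    def overlaps(self, other: "Fragment") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class PlotDataset:
    """Everything an exporter needs to draw one region."""

    region: GenomicRegion
    reference: str
    coverage: Sequence[int]
    fragments: Sequence[Fragment]
    highlights: Sequence[Highlight] = field(default_factory=list)
    packed_values: str = ""
    n_rows: int = 0

    def __post_init__(self) -> None:
        n = len(self.region)
        if len(self.reference) != n or len(self.coverage) != n:
            raise ValueError(
                f"reference ({len(self.reference)}) and coverage "
                f"({len(self.coverage)}) must match region length ({n})"
            )

    @property
    def reads(self) -> list[AlignedRead]:
        return [r for f in self.fragments for r in f.reads]
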