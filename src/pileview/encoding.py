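"""Compact per-read edit encoding and whole-dataset packing.

Instead of shipping every read sequence to the report, each alignment is
re-encoded as the pipe-delimited *edit track* of its differences from the
reference (see :class:`~pileview.core.EditTrack`), e.g.
``50=|3d|10=|1C|1G|iGGT``.  All per-read metadata is then concatenated into
one flat string — records are space-delimited fields joined by the sentinel
``§``, a character the SAM QNAME alphabet cannot contain — and the whole
payload is lz-string-compressed for embedding.  The client decodes all of
this at render time, which is why report size grows only with the payload,
never with the mark/transform structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from .core import (
    AlignedRead,
    Deletion,
    EditOp,
    EditTrack,
    Insertion,
    Match,
    Mismatch,
    ParseError,
    Skip,
)
from .lzstr import compress_utf16, decompress_utf16

SENTINEL = "§"  # §

# CIGAR operation codes as in BAM: M=0, I=1, D=2, N=3, S=4, H=5, P=6, ==7, X=8
_CIGAR_CODES = {op: i for i, op in enumerate("MIDNSHP=X")}

CigarOp = Tuple[Union[int, str], int]


def _cigar_code(op: Union[int, str]) -> int:
    if isinstance(op, str):
        try:
            return _CIGAR_CODES[op]
        except KeyError:
            raise ParseError(f"unknown CIGAR operation {op!r}") from None
    if not 0 <= op <= 8:
        raise ParseError(f"unknown CIGAR operation code {op}")
    return op


def encode_edits(read_sequence: str, cigar: Sequence[CigarOp], ref_slice: str) -> EditTrack:
    """Encode one alignment as an edit track relative to the reference.

    Parameters
    ----------
    read_sequence
        The read bases (SEQ), soft clips included.
    cigar
        ``(op, length)`` pairs; ``op`` is a BAM numeric code or a CIGAR
        letter.  M ops are split into match/mismatch runs by comparing read
        and reference base by base; =/X are taken at face value but still
        re-verified against the reference for mismatch bases.
    ref_slice
        Reference bases starting at the read's leftmost aligned position and
        covering its full aligned span.

    The output is minimal: adjacent match runs merge into one ``<n>=`` token
    and adjacent identical mismatch bases merge into one ``<n><BASE>``
    token, while differing mismatch bases stay separate tokens (the read
    base is recorded — it is what gets drawn).
    """
    read_sequence = read_sequence.upper()
    ref_slice = ref_slice.upper()
    ops: List[EditOp] = []
    qpos = 0  # read cursor
    rpos = 0  # reference cursor (relative to ref_slice)

    def push(op: EditOp) -> None:
        # merge with previous op where the grammar allows
        if ops:
            prev = ops[-1]
            if isinstance(op, Match) and isinstance(prev, Match):
                ops[-1] = Match(prev.length + op.length)
                return
            if (
                isinstance(op, Mismatch)
                and isinstance(prev, Mismatch)
                and prev.base == op.base
            ):
                ops[-1] = Mismatch(prev.length + op.length, op.base)
                return
        ops.append(op)

    def emit_aligned(length: int) -> None:
        nonlocal qpos, rpos
        if qpos + length > len(read_sequence) or rpos + length > len(ref_slice):
            raise ParseError("CIGAR walks past end of read or reference slice")
        for i in range(length):
            rb = ref_slice[rpos + i]
            qb = read_sequence[qpos + i]
            if qb == rb:
                push(Match(1))
            else:
                push(Mismatch(1, qb))
        qpos += length
        rpos += length

    for op, length in cigar:
        code = _cigar_code(op)
        if length < 1:
            raise ParseError(f"CIGAR length must be >= 1, got {length}")
        if code in (0, 7, 8):  # M, =, X — all verified against the reference
            emit_aligned(length)
        elif code == 1:  # I
            if qpos + length > len(read_sequence):
                raise ParseError("insertion walks past end of read")
            push(Insertion(read_sequence[qpos : qpos + length]))
            qpos += length
        elif code == 2:  # D
            push(Deletion(length))
            rpos += length
        elif code == 3:  # N
            push(Skip(length))
            rpos += length
        elif code == 4:  # S — soft clip: consumes read, never drawn
            qpos += length
        # H (5) and P (6) consume nothing and are dropped

    if qpos != len(read_sequence):
        raise ParseError(
            f"CIGAR consumes {qpos} read bases but sequence has {len(read_sequence)}"
        )
    return EditTrack(ops=tuple(ops))


# --------------------------------------------------------------------------
# Decoding to positioned elements
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Element:
    """One positioned alignment element on the reference.

    ``kind`` is one of ``match``, ``mismatch``, ``deletion``, ``skip``,
    ``insertion``.  ``start``/``end`` are 1-based inclusive reference
    coordinates; an insertion sits on the boundary *after* ``start`` (and
    before ``start + 1``), consuming no reference span (``end = start``).
    """

    kind: str
    start: int
    end: int
    base: str = ""  # mismatch read base or insertion sequence


def decode_edits(track_text: str, start_pos: int) -> List[Element]:
    """Expand an edit string into absolutely-positioned elements.

    >>> decode_edits("2=|1A|3d|2=", 50)[:2]
    [Element(kind='match', start=50, end=51, base=''), Element(kind='mismatch', start=52, end=52, base='A')]
    """
    track = EditTrack.parse(track_text)
    elements: List[Element] = []
    pos = start_pos
    for op in track.ops:
        if isinstance(op, Match):
            elements.append(Element("match", pos, pos + op.length - 1))
            pos += op.length
        elif isinstance(op, Mismatch):
            # one element per base so each draws as its own colored cell
            for i in range(op.length):
                elements.append(Element("mismatch", pos + i, pos + i, op.base))
            pos += op.length
        elif isinstance(op, Deletion):
            elements.append(Element("deletion", pos, pos + op.length - 1))
            pos += op.length
        elif isinstance(op, Skip):
            elements.append(Element("skip", pos, pos + op.length - 1))
            pos += op.length
        else:  # Insertion: marker between pos-1 and pos
            elements.append(Element("insertion", pos - 1, pos - 1, op.sequence))
    return elements


# --------------------------------------------------------------------------
# Packing
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PackedValues:
    """The flat ``§``-joined payload plus its record count."""

    payload: str
    n_reads: int

    def __post_init__(self) -> None:
        if self.n_reads:
            records = self.payload.split(SENTINEL)
            if len(records) != self.n_reads:
                raise ValueError(
                    f"payload splits into {len(records)} records, expected {self.n_reads}"
                )


def pack_reads(reads: Sequence[AlignedRead]) -> PackedValues:
    """Pack reads into one flat string: ``name pos mapq strand edits`` per
    record, records joined by ``§``.

    Valid SAM names can never contain a space or the sentinel, but this is
    asserted defensively — a corrupted name would silently shear the payload.
    """
    records = []
    for read in reads:
        if SENTINEL in read.name or " " in read.name:
            raise ValueError(f"read name {read.name!r} collides with packing delimiters")
        records.append(
            f"{read.name} {read.pos} {read.mapq} {read.strand} {read.edits.text}"
        )
    return PackedValues(payload=SENTINEL.join(records), n_reads=len(records))


def unpack_reads(packed: PackedValues) -> List[Tuple[str, int, int, str, str]]:
    """Exact inverse of :func:`pack_reads` on the packed fields."""
    if packed.n_reads == 0:
        return []
    out = []
    for i, record in enumerate(packed.payload.split(SENTINEL)):
        fields = record.split(" ")
        if len(fields) != 5:
            raise ParseError(
                f"record {i} has {len(fields)} fields, expected 5: {record!r}"
            )
        name, pos, mapq, strand, edits = fields
        if strand not in ("+", "-"):
            raise ParseError(f"record {i}: invalid strand {strand!r}")
        out.append((name, int(pos), int(mapq), strand, edits))
    return out


def compress_payload(text: str) -> str:
    """lz-string (UTF-16-safe dialect) compression of an arbitrary string."""
    return compress_utf16(text)


def decompress_payload(compressed: str) -> str:
    return decompress_utf16(compressed)
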