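"""Synthetic alignment fixtures with ground-truth manifests.

Generates small random references and SAM/BAM files with controlled
mismatch/indel structure, pairing, and MAPQ distribution.  Every read's
true position, CIGAR, and expected edit string are recorded in a manifest
TSV, so the full pipeline can be checked end-to-end through real file I/O.

Files are written through pysam's writers (never hand-assembled text), so
flag and index semantics are always valid.  All randomness flows from one
``seed`` argument.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .core import Deletion, EditOp, EditTrack, Insertion, Match, Mismatch

_BASES = "ACGT"


def make_reference(
    length: int, seed: int, out_path: os.PathLike, chrom: str = "ref"
) -> str:
    """Write a uniform-random FASTA of ``length`` bases plus its FAI index.

    Returns the generated sequence.  Deterministic per seed.
    """
    if length < 1:
        raise ValueError("reference length must be >= 1")
    rng = random.Random(seed)
    seq = "".join(rng.choice(_BASES) for _ in range(length))
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, length, 60):
            fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(out_path))
    return seq


@dataclass(frozen=True)
class ReadProfile:
    """Error/pairing profile for generated reads.

    Rates are per reference base walked; ``mapq_distribution`` maps MAPQ
    values to sampling weights.  Defaults emulate a well-behaved short-read
    Illumina-style library: 100 bp reads, ~1% mismatches, rare short
    indels, fully paired with a 300 bp mean insert, mostly confident
    mappings with a tail of uncertain ones.
    """

    read_length: int = 100
    mismatch_rate: float = 0.01
    indel_rate: float = 0.001
    paired_fraction: float = 1.0
    insert_size_mean: int = 300
    insert_size_sd: int = 30
    mapq_distribution: Tuple[Tuple[int, float], ...] = ((60, 0.85), (37, 0.08), (20, 0.04), (5, 0.03))


@dataclass(frozen=True)
class ReadRecord:
    """Manifest entry: the ground truth for one generated read."""

    name: str
    chrom: str
    pos: int  # 1-based leftmost aligned base
    mapq: int
    strand: str
    cigar: Tuple[Tuple[int, int], ...]
    seq: str
    edit_text: str  # expected edit-track rendering
    is_paired: bool
    mate_pos: Optional[int]


@dataclass
class Manifest:
    """Ground truth for a generated alignment file."""

    chrom: str
    reads: List[ReadRecord] = field(default_factory=list)

    def write_tsv(self, path: os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("name\tchrom\tpos\tmapq\tstrand\tcigar\tedits\tmate_pos\n")
            for r in self.reads:
                cigar = "".join(f"{ln}{'MIDNSHP=X'[op]}" for op, ln in r.cigar)
                fh.write(
                    f"{r.name}\t{r.chrom}\t{r.pos}\t{r.mapq}\t{r.strand}\t"
                    f"{cigar}\t{r.edit_text}\t{r.mate_pos if r.mate_pos else ''}\n"
                )


def _simulate_read(
    reference: str, start0: int, read_length: int, profile: ReadProfile, rng: random.Random
) -> Tuple[str, Tuple[Tuple[int, int], ...], List[EditOp]]:
    """One read: walk the reference emitting matches/mismatches/indels.

    Returns (sequence, CIGAR as (op, len) numeric pairs, true edit ops).
    The CIGAR uses M for aligned stretches so the encoder's base-comparison
    path is exercised by default.
    """
    seq_parts: List[str] = []
    ops: List[EditOp] = []
    cigar: List[Tuple[int, int]] = []

    def push_cigar(code: int, length: int) -> None:
        if cigar and cigar[-1][0] == code:
            cigar[-1] = (code, cigar[-1][1] + length)
        else:
            cigar.append((code, length))

    def push_op(op: EditOp) -> None:
        if ops and isinstance(op, Match) and isinstance(ops[-1], Match):
            ops[-1] = Match(ops[-1].length + op.length)
        elif (
            ops
            and isinstance(op, Mismatch)
            and isinstance(ops[-1], Mismatch)
            and ops[-1].base == op.base
        ):
            ops[-1] = Mismatch(ops[-1].length + op.length, op.base)
        else:
            ops.append(op)

    rpos = start0
    emitted = 0
    while emitted < read_length and rpos < len(reference):
        roll = rng.random()
        if roll < profile.indel_rate and emitted > 0:
            length = rng.randint(1, 3)
            if rng.random() < 0.5 and emitted + length <= read_length:
                ins = "".join(rng.choice(_BASES) for _ in range(length))
                seq_parts.append(ins)
                push_cigar(1, length)
                push_op(Insertion(ins))
                emitted += length
            elif rpos + length < len(reference):
                push_cigar(2, length)
                push_op(Deletion(length))
                rpos += length
            continue
        ref_base = reference[rpos].upper()
        if roll < profile.indel_rate + profile.mismatch_rate:
            base = rng.choice([b for b in _BASES if b != ref_base])
            push_op(Mismatch(1, base))
        else:
            base = ref_base
            push_op(Match(1))
        seq_parts.append(base)
        push_cigar(0, 1)
        rpos += 1
        emitted += 1

    return "".join(seq_parts), tuple(cigar), ops


def _sample_mapq(profile: ReadProfile, rng: random.Random) -> int:
    values = [v for v, _ in profile.mapq_distribution]
    weights = [w for _, w in profile.mapq_distribution]
    return rng.choices(values, weights=weights, k=1)[0]


def make_reads(
    reference: str,
    n: int,
    profile: ReadProfile,
    seed: int,
    out_path: os.PathLike,
    chrom: str = "ref",
    fmt: str = "bam",
) -> Manifest:
    """Generate ``n`` reads (pairs count as two) into a SAM or BAM file.

    BAM output is coordinate-sorted and indexed.  Read positions are
    uniform over the feasible span; paired reads get a mate at
    insert-size distance (clamped to the reference).  Returns the manifest
    of ground truth, also written as ``<out_path>.manifest.tsv``.
    """
    if profile.read_length > len(reference):
        raise ValueError(
            f"read_length {profile.read_length} exceeds reference length {len(reference)}"
        )
    rng = random.Random(seed)
    manifest = Manifest(chrom=chrom)
    records: List[ReadRecord] = []

    i = 0
    serial = 0
    while i < n:
        serial += 1
        name = f"read{serial:05d}"
        paired = rng.random() < profile.paired_fraction and i + 1 < n
        max_start0 = len(reference) - profile.read_length
        start0 = rng.randint(0, max_start0)
        seq1, cigar1, ops1 = _simulate_read(
            reference, start0, profile.read_length, profile, rng
        )
        mapq = _sample_mapq(profile, rng)
        if paired:
            insert = max(
                profile.read_length + 1,
                int(rng.gauss(profile.insert_size_mean, profile.insert_size_sd)),
            )
            mate_start0 = min(start0 + insert - profile.read_length, max_start0)
            seq2, cigar2, ops2 = _simulate_read(
                reference, mate_start0, profile.read_length, profile, rng
            )
            records.append(
                ReadRecord(
                    name, chrom, start0 + 1, mapq, "+", cigar1, seq1,
                    EditTrack(tuple(ops1)).text, True, mate_start0 + 1,
                )
            )
            records.append(
                ReadRecord(
                    name, chrom, mate_start0 + 1, mapq, "-", cigar2, seq2,
                    EditTrack(tuple(ops2)).text, True, start0 + 1,
                )
            )
            i += 2
        else:
            records.append(
                ReadRecord(
                    name, chrom, start0 + 1, mapq, "+", cigar1, seq1,
                    EditTrack(tuple(ops1)).text, False, None,
                )
            )
            i += 1

    manifest.reads = sorted(records, key=lambda r: (r.pos, r.name))
    _write_alignments(manifest, len(reference), out_path, fmt)
    manifest.write_tsv(str(out_path) + ".manifest.tsv")
    return manifest


def _write_alignments(
    manifest: Manifest, ref_length: int, out_path: os.PathLike, fmt: str
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": manifest.chrom, "LN": ref_length}],
    }
    out_path = Path(out_path)
    mode = "wb" if fmt == "bam" else "w"
    tmp = out_path.with_suffix(out_path.suffix + ".unsorted") if fmt == "bam" else out_path
    with pysam.AlignmentFile(str(tmp), mode, header=header) as af:
        for rec in manifest.reads:
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = rec.name
            seg.query_sequence = rec.seq
            seg.reference_id = 0
            seg.reference_start = rec.pos - 1
            seg.mapping_quality = rec.mapq
            seg.cigartuples = list(rec.cigar)
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            flag = 0
            if rec.strand == "-":
                flag |= 0x10
            if rec.is_paired:
                flag |= 0x1 | 0x2
                flag |= 0x80 if rec.strand == "-" else 0x40
                flag |= 0x20 if rec.strand == "+" else 0
                seg.next_reference_id = 0
                seg.next_reference_start = rec.mate_pos - 1
            else:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            seg.flag = flag
            af.write(seg)
    if fmt == "bam":
        pysam.sort("-o", str(out_path), str(tmp))
        os.remove(tmp)
        pysam.index(str(out_path))


def make_worked_example(out_dir: os.PathLike, seed: int = 0) -> Tuple[Path, Path]:
    """A scripted single-read fixture whose edit track is
    ``50=|3d|10=|1C|1G|iGGT``: 50 matches, a 3 bp deletion, 10 matches, a C
    and a G mismatch, and a trailing GGT insertion.

    Returns (fasta_path, sam_path).
    """
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    # reference: 1-based; read starts at pos 11
    ref = [rng.choice(_BASES) for _ in range(120)]
    start0 = 10
    # positions start0..start0+49 match; deletion of 3; 10 matches;
    # then two mismatching positions; ensure ref differs from C then G
    mm1 = start0 + 63
    mm2 = start0 + 64
    ref[mm1] = rng.choice([b for b in _BASES if b != "C"])
    ref[mm2] = rng.choice([b for b in _BASES if b != "G"])
    ref_seq = "".join(ref)

    read_seq = (
        ref_seq[start0 : start0 + 50]
        + ref_seq[start0 + 53 : start0 + 63]
        + "C"
        + "G"
        + "GGT"
    )
    cigar = ((0, 50), (2, 3), (0, 12), (1, 3))

    fasta_path = out_dir / "worked_example.fa"
    with open(fasta_path, "w") as fh:
        fh.write(">ref\n")
        for i in range(0, len(ref_seq), 60):
            fh.write(ref_seq[i : i + 60] + "\n")
    pysam.faidx(str(fasta_path))

    sam_path = out_dir / "worked_example.sam"
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "ref", "LN": len(ref_seq)}]}
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as af:
        seg = pysam.AlignedSegment(af.header)
        seg.query_name = "example"
        seg.query_sequence = read_seq
        seg.reference_id = 0
        seg.reference_start = start0
        seg.mapping_quality = 60
        seg.cigartuples = list(cigar)
        seg.flag = 0
        af.write(seg)
    return fasta_path, sam_path
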