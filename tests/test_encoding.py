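"""Edit-track codec against an independent per-base CIGAR-walk oracle,
plus packing/compression roundtrips."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pileview.core import AlignedRead, EditTrack, ParseError
from pileview.encoding import (
    PackedValues,
    SENTINEL,
    decode_edits,
    encode_edits,
    pack_reads,
    unpack_reads,
)

# --------------------------------------------------------------------------
# Independent oracle: a literal per-base CIGAR interpreter.  It shares no
# code with the encoder; each alignment becomes a list of columns.
# --------------------------------------------------------------------------


def cigar_columns(seq, cigar, ref_slice, start_pos=1):
    """Columns of the alignment: one tuple per reference base or insertion."""
    cols = []
    q = r = 0
    seq = seq.upper()
    ref_slice = ref_slice.upper()
    for op, length in cigar:
        if op in (0, 7, 8):  # M / = / X
            for i in range(length):
                cols.append(("aligned", start_pos + r + i, seq[q + i], ref_slice[r + i]))
            q += length
            r += length
        elif op == 1:  # I: sits on the boundary after the previous ref base
            cols.append(("ins", start_pos + r - 1, seq[q : q + length]))
            q += length
        elif op == 2:  # D
            for i in range(length):
                cols.append(("del", start_pos + r + i))
            r += length
        elif op == 3:  # N
            for i in range(length):
                cols.append(("skip", start_pos + r + i))
            r += length
        elif op == 4:  # S
            q += length
    return cols


def columns_from_track(track_text, ref_slice, start_pos=1):
    """The same column list, reconstructed from an encoded track."""
    cols = []
    for el in decode_edits(track_text, start_pos):
        if el.kind == "match":
            for p in range(el.start, el.end + 1):
                base = ref_slice[p - start_pos]
                cols.append(("aligned", p, base, base))
        elif el.kind == "mismatch":
            cols.append(("aligned", el.start, el.base, ref_slice[el.start - start_pos]))
        elif el.kind == "deletion":
            for p in range(el.start, el.end + 1):
                cols.append(("del", p))
        elif el.kind == "skip":
            for p in range(el.start, el.end + 1):
                cols.append(("skip", p))
        else:
            cols.append(("ins", el.start, el.base))
    return cols


def random_alignment(rng):
    """A random (seq, cigar, ref_slice) triple with a well-formed CIGAR."""
    ref_len = 0
    seq = []
    cigar = []
    ref = []
    n_ops = rng.randint(1, 12)
    prev = None
    for i in range(n_ops):
        choices = ["M", "M", "M", "I", "D", "N", "S"]
        if prev in ("I", "D", "N"):  # no adjacent gap ops, as in real CIGARs
            choices = ["M"]
        if i in (0, n_ops - 1) and "M" not in choices:
            choices = ["M"]
        op = rng.choice(choices)
        length = rng.randint(1, 20)
        if op == "M":
            for _ in range(length):
                rb = rng.choice("ACGT")
                ref.append(rb)
                # ~20% mismatches to exercise run splitting
                seq.append(rng.choice("ACGT") if rng.random() < 0.2 else rb)
            cigar.append((0, length))
        elif op == "I":
            seq.extend(rng.choice("ACGT") for _ in range(length))
            cigar.append((1, length))
        elif op == "D":
            ref.extend(rng.choice("ACGT") for _ in range(length))
            cigar.append((2, length))
        elif op == "N":
            ref.extend(rng.choice("ACGT") for _ in range(length))
            cigar.append((3, length))
        else:  # S only at the ends
            if i in (0, n_ops - 1):
                seq.extend(rng.choice("ACGT") for _ in range(length))
                cigar.append((4, length))
            else:
                continue
        prev = op
    if not any(op in (0, 7, 8) for op, _ in cigar):
        cigar.append((0, 5))
        for _ in range(5):
            rb = rng.choice("ACGT")
            ref.append(rb)
            seq.append(rb)
    return "".join(seq), cigar, "".join(ref)


class TestEncodeDecode:
    def test_worked_example(self):
        """50 matches, 3 bp deletion, 10 matches, C and G mismatches, GGT insertion."""
        rng = random.Random(5)
        ref = [rng.choice("ACGT") for _ in range(65)]
        ref[63] = rng.choice([b for b in "ACGT" if b != "C"])  # read carries C here
        ref[64] = rng.choice([b for b in "ACGT" if b != "G"])  # and G here
        ref = "".join(ref)
        # 50 matches | 3 bp deletion | 10 matches + C + G mismatches | GGT inserted
        read = ref[:50] + ref[53:63] + "CG" + "GGT"
        cigar = [(0, 50), (2, 3), (0, 12), (1, 3)]
        track = encode_edits(read, cigar, ref)
        assert track.text == "50=|3d|10=|1C|1G|iGGT"

    def test_identity_alignment(self):
        ref = "ACGT" * 25
        assert encode_edits(ref, [(0, 100)], ref).text == "100="

    def test_soft_clips_dropped(self):
        ref = "ACGTACGTAC"
        read = "TTT" + ref + "GG"
        track = encode_edits(read, [(4, 3), (0, 10), (4, 2)], ref)
        assert track.text == "10="

    def test_adjacent_identical_mismatches_merge(self):
        ref = "AAAA"
        read = "GGAA"
        assert encode_edits(read, [(0, 4)], ref).text == "2G|2="

    def test_adjacent_different_mismatches_stay_separate(self):
        ref = "TTTT"
        read = "CGTT"
        assert encode_edits(read, [(0, 4)], ref).text == "1C|1G|2="

    def test_explicit_eq_x_cigars(self):
        ref = "ACGTACGT"
        read = "ACGTACGA"
        assert encode_edits(read, [(7, 7), (8, 1)], ref).text == "7=|1A"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParseError):
            encode_edits("ACGT", [(0, 10)], "ACGTACGTAC")
        with pytest.raises(ParseError):
            encode_edits("ACGTACGT", [(0, 4)], "ACGT")

    @pytest.mark.parametrize("seed", range(5))
    def test_codec_matches_cigar_walk_oracle(self, seed):
        """encode→decode reproduces the oracle's alignment column-for-column
        on 200 random triples per seed (1000 total)."""
        rng = random.Random(seed)
        for _ in range(200):
            seq, cigar, ref = random_alignment(rng)
            start = rng.randint(1, 10**6)
            track = encode_edits(seq, cigar, ref)
            assert columns_from_track(track.text, ref, start) == cigar_columns(
                seq, cigar, ref, start
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_minimality_no_mergeable_neighbors(self, seed):
        rng = random.Random(seed + 100)
        for _ in range(100):
            seq, cigar, ref = random_alignment(rng)
            tokens = encode_edits(seq, cigar, ref).text.split("|")
            for a, b in zip(tokens, tokens[1:]):
                if a.endswith("=") and b.endswith("="):
                    pytest.fail(f"adjacent match tokens: {a}|{b}")
                if a[-1] in "ACGTN" and a[0] != "i" and b[-1] in "ACGTN" and b[0] != "i":
                    assert a[-1] != b[-1], f"adjacent same-base mismatch tokens: {a}|{b}"

    def test_compactness_for_lightly_edited_reads(self):
        """~1% edits on ≥100 bp reads → edit string < 20% of read length.

        Storing only edit operations (never the read sequence) keeps the
        representation a small fraction of the raw bases at typical
        sequencing error rates; each mismatch costs ~8 characters of
        tokens, so the 20% bound holds for edit densities up to ~2.5%.
        """
        rng = random.Random(77)
        for _ in range(50):
            n = rng.randint(100, 300)
            ref = "".join(rng.choice("ACGT") for _ in range(n))
            read = list(ref)
            for _ in range(max(1, round(n * 0.01))):
                i = rng.randrange(n)
                read[i] = rng.choice([b for b in "ACGT" if b != ref[i]])
            track = encode_edits("".join(read), [(0, n)], ref)
            assert len(track.text) < 0.2 * n


class TestDecodePositions:
    def test_single_match_block(self):
        els = decode_edits("10=", 100)
        assert len(els) == 1
        assert (els[0].kind, els[0].start, els[0].end) == ("match", 100, 109)

    def test_mixed_track_hand_walk(self):
        els = decode_edits("2=|1A|3d|2=", 50)
        assert [(e.kind, e.start, e.end) for e in els] == [
            ("match", 50, 51),
            ("mismatch", 52, 52),
            ("deletion", 53, 55),
            ("match", 56, 57),
        ]

    def test_insertion_sits_between_flanking_bases(self):
        els = decode_edits("5=|iACG|5=", 10)
        ins = [e for e in els if e.kind == "insertion"][0]
        assert ins.start == ins.end == 14  # boundary between 14 and 15
        assert ins.base == "ACG"
        # total reference span unaffected by the insertion
        assert EditTrack.parse("5=|iACG|5=").ref_span == 10

    def test_grammar_violation_reports_token(self):
        with pytest.raises(ParseError, match="index 1"):
            decode_edits("5=|oops|3d", 1)


class TestPacking:
    def _read(self, name="r1", pos=100, mapq=60, strand="+", edits="10="):
        return AlignedRead(
            name=name, pos=pos, mapq=mapq, strand=strand, edits=EditTrack.parse(edits)
        )

    def test_single_record_format(self):
        packed = pack_reads([self._read()])
        assert packed.payload == "r1 100 60 + 10="
        assert packed.n_reads == 1

    def test_records_joined_by_sentinel(self):
        packed = pack_reads([self._read("r1"), self._read("r2", pos=200)])
        assert packed.payload.count(SENTINEL) == 1
        assert packed.payload == f"r1 100 60 + 10={SENTINEL}r2 200 60 + 10="

    def test_empty_list(self):
        packed = pack_reads([])
        assert packed.payload == "" and packed.n_reads == 0
        assert unpack_reads(packed) == []

    def test_unpack_is_inverse(self):
        rng = random.Random(3)
        reads = [
            self._read(
                name=f"frag-{i}/1",
                pos=rng.randint(1, 10**6),
                mapq=rng.randint(0, 254),
                strand=rng.choice("+-"),
                edits=rng.choice(["10=", "5=|1A|4=", "3=|2d|5=", "1=|iTT|9="]),
            )
            for i in range(100)
        ]
        packed = pack_reads(reads)
        assert unpack_reads(packed) == [
            (r.name, r.pos, r.mapq, r.strand, r.edits.text) for r in reads
        ]

    def test_wrong_field_count_rejected(self):
        with pytest.raises(ParseError, match="record 0"):
            unpack_reads(PackedValues(payload="one two three four five six seven", n_reads=1))

    def test_sentinel_in_name_rejected(self):
        # cannot be built as an AlignedRead at all (QNAME alphabet)
        with pytest.raises(ParseError):
            self._read(name=f"bad{SENTINEL}name")
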