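"""Fragment assembly, subsampling, row packing (vs. exhaustive coloring),
and coverage (vs. a naive counting oracle)."""

import itertools
import random

import numpy as np
import pytest

from pileview.core import AlignedRead, EditTrack, Fragment, GenomicRegion
from pileview.layout import (
    assemble_fragments,
    assign_rows,
    compute_coverage,
    subsample_fragments,
)


def _read(name, pos, span, mapq=60, strand="+"):
    return AlignedRead(
        name=name, pos=pos, mapq=mapq, strand=strand, edits=EditTrack.parse(f"{span}=")
    )


def _frag(name, start, end):
    return Fragment(reads=(_read(name, start, end - start + 1),))


# --------------------------------------------------------------------------
# Oracles
# --------------------------------------------------------------------------


def chromatic_number_exhaustive(intervals):
    """Minimum colors for the interval-overlap graph, by exhaustive search.

    Backtracking over all colorings (with the standard first-use symmetry
    break, which discards only relabelings); independent of the greedy
    implementation under test.
    """
    n = len(intervals)
    adj = [
        [
            j
            for j in range(n)
            if j != i
            and intervals[i][0] <= intervals[j][1]
            and intervals[j][0] <= intervals[i][1]
        ]
        for i in range(n)
    ]

    def feasible(k):
        colors = [-1] * n

        def bt(i, used):
            if i == n:
                return True
            for c in range(min(used + 1, k)):
                if all(colors[j] != c for j in adj[i]):
                    colors[i] = c
                    if bt(i + 1, max(used, c + 1)):
                        return True
                    colors[i] = -1
            return False

        return bt(0, 0)

    for k in range(1, n + 1):
        if feasible(k):
            return k
    return n


def max_point_overlap(intervals):
    """ω of the interval graph: max fragments covering one base (sweep)."""
    events = []
    for start, end in intervals:
        events.append((start, 1))
        events.append((end + 1, -1))
    depth = best = 0
    for _, delta in sorted(events):
        depth += delta
        best = max(best, depth)
    return best


def naive_coverage(reads, region):
    """Nested loop over reads × positions, counting aligned bases only."""
    cov = [0] * len(region)
    for read in reads:
        pos = read.pos
        for token in read.edits.text.split("|"):
            if not token:
                continue
            if token.startswith("i"):
                continue
            length, kind = int(token[:-1]), token[-1]
            if kind in ("=",) or kind in "ACGTN":
                for p in range(pos, pos + length):
                    if region.start <= p <= region.end:
                        cov[p - region.start] += 1
            pos += length
    return cov


# --------------------------------------------------------------------------
# Fragment assembly
# --------------------------------------------------------------------------


class TestAssembleFragments:
    def test_mates_form_one_fragment_spanning_both(self):
        region = GenomicRegion("1", 1, 1000)
        reads = [_read("r1", 100, 50), _read("r1", 300, 50, strand="-")]
        frags = assemble_fragments(reads, region)
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (100, 349)

    def test_unpaired_read_is_singleton(self):
        region = GenomicRegion("1", 1, 100)
        frags = assemble_fragments([_read("solo", 10, 50)], region)
        assert len(frags) == 1 and (frags[0].start, frags[0].end) == (10, 59)

    def test_three_reads_one_name_is_corrupt_input(self):
        region = GenomicRegion("1", 1, 1000)
        reads = [_read("dup", 1, 10), _read("dup", 50, 10), _read("dup", 99, 10)]
        with pytest.raises(ValueError, match="3 primary alignments"):
            assemble_fragments(reads, region)


class TestSubsample:
    def _frags(self, n, seed=0):
        rng = random.Random(seed)
        return [_frag(f"f{i:04d}", rng.randint(1, 5000), rng.randint(5001, 6000)) for i in range(n)]

    def test_under_threshold_is_identity(self):
        frags = self._frags(10)
        assert subsample_fragments(frags, max_depth=20) == sorted(
            frags, key=lambda f: (f.start, f.name)
        )

    def test_fixed_seed_reproducible(self):
        frags = self._frags(1000)
        a = subsample_fragments(frags, max_depth=100, seed=42)
        b = subsample_fragments(frags, max_depth=100, seed=42)
        assert [f.name for f in a] == [f.name for f in b]
        assert len(a) == 100

    def test_different_seeds_differ(self):
        frags = self._frags(1000)
        a = subsample_fragments(frags, max_depth=100, seed=1)
        b = subsample_fragments(frags, max_depth=100, seed=2)
        assert [f.name for f in a] != [f.name for f in b]

    def test_plot_all_retains_everything(self):
        frags = self._frags(2000)
        assert len(subsample_fragments(frags, max_depth=10, plot_all=True)) == 2000

    def test_output_order_is_start_then_name(self):
        frags = self._frags(500)
        out = subsample_fragments(frags, max_depth=50, seed=7)
        assert [(f.start, f.name) for f in out] == sorted((f.start, f.name) for f in out)


class TestAssignRows:
    def test_single_fragment(self):
        frags = [_frag("a", 1, 10)]
        assignment = assign_rows(frags)
        assert assignment.r == 1 and frags[0].row == 1

    def test_three_interval_example(self):
        frags = [_frag("a", 1, 10), _frag("b", 5, 15), _frag("c", 12, 20)]
        assignment = assign_rows(frags)
        assert assignment.r == 2
        assert frags[0].row == frags[2].row  # [1,10] and [12,20] share a row
        assert frags[1].row != frags[0].row

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_chromatic_number(self, seed):
        """Greedy row count equals brute-force χ on 50 instances of ≤8 fragments."""
        rng = random.Random(seed)
        for _ in range(50):
            n = rng.randint(1, 8)
            intervals = []
            for _ in range(n):
                s = rng.randint(1, 40)
                intervals.append((s, s + rng.randint(0, 15)))
            frags = [_frag(f"f{i}", s, e) for i, (s, e) in enumerate(intervals)]
            assignment = assign_rows(frags)
            assert assignment.r == chromatic_number_exhaustive(intervals)
            _assert_feasible(frags)

    @pytest.mark.parametrize("seed", range(3))
    def test_row_count_equals_clique_number_at_scale(self, seed):
        """r = maximum point overlap on larger random instances (interval graphs: χ=ω)."""
        rng = random.Random(seed + 50)
        for _ in range(30):
            n = rng.randint(10, 500)
            intervals = []
            for _ in range(n):
                s = rng.randint(1, 10_000)
                intervals.append((s, s + rng.randint(1, 600)))
            frags = [_frag(f"f{i:04d}", s, e) for i, (s, e) in enumerate(intervals)]
            assert assign_rows(frags).r == max_point_overlap(intervals)

    def test_permutation_invariance_of_row_count(self):
        rng = random.Random(9)
        intervals = [(rng.randint(1, 300), 0) for _ in range(60)]
        intervals = [(s, s + rng.randint(1, 80)) for s, _ in intervals]
        frags = [_frag(f"f{i:03d}", s, e) for i, (s, e) in enumerate(intervals)]
        r0 = assign_rows(frags).r
        for _ in range(5):
            rng.shuffle(frags)
            assert assign_rows(frags).r == r0

    def test_identical_input_gives_identical_assignment(self):
        frags1 = [_frag(f"f{i}", i * 3, i * 3 + 10) for i in range(30)]
        frags2 = [_frag(f"f{i}", i * 3, i * 3 + 10) for i in range(30)]
        assert assign_rows(frags1).rows == assign_rows(frags2).rows

    def test_pair_linker_gap_blocks_the_row(self):
        """A fragment's interval covers the unsequenced insert between mates."""
        pair = Fragment(reads=(_read("p", 1, 50), _read("p", 500, 50)))
        inner = _frag("inner", 100, 200)  # fits in the linker gap
        assert assign_rows([pair, inner]).r == 2


def _assert_feasible(frags):
    for a, b in itertools.combinations(frags, 2):
        if a.row == b.row:
            assert not a.overlaps(b), f"{a.name} and {b.name} overlap on row {a.row}"


class TestCoverage:
    def test_single_read_all_ones(self):
        region = GenomicRegion("1", 100, 109)
        cov = compute_coverage([_read("r", 100, 10)], region)
        assert cov.tolist() == [1] * 10

    def test_two_identical_reads_additive(self):
        region = GenomicRegion("1", 100, 109)
        cov = compute_coverage([_read("a", 100, 10), _read("b", 100, 10)], region)
        assert cov.tolist() == [2] * 10

    def test_deletion_and_skip_do_not_count(self):
        region = GenomicRegion("1", 1, 20)
        read = AlignedRead(
            name="r", pos=1, mapq=60, strand="+", edits=EditTrack.parse("5=|3d|2=|5n|5=")
        )
        cov = compute_coverage([read], region)
        assert cov.tolist() == [1] * 5 + [0] * 3 + [1] * 2 + [0] * 5 + [1] * 5

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_counting_oracle(self, seed):
        rng = random.Random(seed)
        region = GenomicRegion("1", 50, 449)
        reads = []
        for i in range(50):
            pos = rng.randint(1, 470)
            parts, span = [], 0
            for _ in range(rng.randint(1, 4)):
                n = rng.randint(1, 30)
                kind = rng.choice(["=", "=", "A", "d", "n"])
                parts.append(f"{n}{kind}")
                span += n
            reads.append(
                AlignedRead(
                    name=f"r{i}", pos=pos, mapq=60, strand="+",
                    edits=EditTrack.parse("|".join(parts)),
                )
            )
        assert compute_coverage(reads, region).tolist() == naive_coverage(reads, region)

    def test_conservation_of_aligned_bases(self):
        """Σ coverage = Σ matched+mismatched bases (region covering all reads)."""
        region = GenomicRegion("1", 1, 1000)
        reads = [_read(f"r{i}", 1 + i * 7, 50) for i in range(20)]
        total = sum(
            op.length
            for r in reads
            for op in r.edits.ops
            if type(op).__name__ in ("Match", "Mismatch")
        )
        assert int(compute_coverage(reads, region).sum()) == total
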