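"""Interval model, BED I/O, and peak-set algebra against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cistromekit.intervals import (
    BedParseError,
    GenomicInterval,
    PeakSet,
    classify_dynamics,
    intersect_partition,
    merge_intervals,
    read_bed,
    sort_and_validate,
    write_bed,
)

from conftest import brute_force_overlaps, random_peaks


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)

    def test_overlap_is_strand_blind_and_half_open(self):
        a = GenomicInterval("chr1", 100, 200, strand="+")
        assert a.overlaps(GenomicInterval("chr1", 199, 300, strand="-"))
        assert not a.overlaps(GenomicInterval("chr1", 200, 300))
        assert not a.overlaps(GenomicInterval("chr2", 100, 200))


class TestBedIO:
    def test_three_column_defaults(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        ps = read_bed(p)
        assert ps[0] == GenomicInterval("chr1", 100, 200, ".", 0.0, ".")

    def test_unsorted_input_is_sorted(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2\t5\t10\nchr1\t50\t60\nchr1\t5\t10\n")
        ps = read_bed(p)
        assert [iv.key() for iv in ps] == [
            ("chr1", 5, 10),
            ("chr1", 50, 60),
            ("chr2", 5, 10),
        ]

    def test_degenerate_interval_reports_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t300\t300\n")
        with pytest.raises(BedParseError, match=":2:"):
            read_bed(p)

    def test_roundtrip(self, tmp_path):
        ps = random_peaks(np.random.default_rng(0), 50)
        write_bed(ps, tmp_path / "x.bed")
        assert read_bed(tmp_path / "x.bed").intervals == ps.intervals


class TestSortAndValidate:
    def test_duplicate_retained_once_with_report(self):
        iv = GenomicInterval("chr1", 10, 20, "a")
        dup = GenomicInterval("chr1", 10, 20, "b")
        with pytest.warns(UserWarning, match="duplicate"):
            out = sort_and_validate(PeakSet([iv, dup]))
        assert len(out) == 1

    def test_valid_set_unchanged(self):
        ps = random_peaks(np.random.default_rng(1), 100)
        assert sort_and_validate(ps).intervals == ps.intervals

    def test_order_matches_naive_sort_oracle(self):
        rng = np.random.default_rng(2)
        ps = random_peaks(rng, 1000)
        oracle = sorted(ps.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        assert sort_and_validate(ps).intervals == oracle


class TestIntersectPartition:
    def test_single_overlap_pair(self):
        a = PeakSet([GenomicInterval("chr1", 100, 200)], "A")
        b = PeakSet([GenomicInterval("chr1", 150, 250)], "B")
        part = intersect_partition(a, b)
        assert len(part.a_common) == 1 and len(part.b_common) == 1
        assert len(part.a_unique) == 0 and len(part.b_unique) == 0
        assert part.pair_index == {0: [0]}

    def test_empty_b_gives_all_a_unique(self):
        a = random_peaks(np.random.default_rng(3), 20)
        part = intersect_partition(a, PeakSet([], "B"))
        assert part.a_unique.intervals == a.intervals
        assert len(part.a_common) == len(part.b_common) == len(part.b_unique) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_allpairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peaks(rng, 500, max_pos=200_000, label="A")
        b = random_peaks(rng, 500, max_pos=200_000, label="B")
        part = intersect_partition(a, b)
        a_hits = brute_force_overlaps(a, b)
        b_hits = brute_force_overlaps(b, a)
        assert [iv for iv, h in zip(a, a_hits) if h] == part.a_common.intervals
        assert [iv for iv, h in zip(a, a_hits) if not h] == part.a_unique.intervals
        assert [iv for iv, h in zip(b, b_hits) if h] == part.b_common.intervals
        assert [iv for iv, h in zip(b, b_hits) if not h] == part.b_unique.intervals
        # counts are consistent partitions
        assert len(part.a_unique) + len(part.a_common) == len(a)
        assert len(part.b_unique) + len(part.b_common) == len(b)
        # symmetric consistency
        assert bool(len(part.a_common)) == bool(len(part.b_common))
        # pair_index entries really overlap
        for ai, bjs in part.pair_index.items():
            assert all(a[ai].overlaps(b[bj]) for bj in bjs)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 50)), max_size=30
        ),
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 50)), max_size=30
        ),
    )
    def test_partition_property(self, a_raw, b_raw):
        a = PeakSet([GenomicInterval("c", s, s + w) for s, w in a_raw], "A")
        b = PeakSet([GenomicInterval("c", s, s + w) for s, w in b_raw], "B")
        part = intersect_partition(a, b)
        assert len(part.a_unique) + len(part.a_common) == len(a)
        assert len(part.b_unique) + len(part.b_common) == len(b)
        for iv in part.a_unique:
            assert not any(iv.overlaps(x) for x in b)
        for iv in part.a_common:
            assert any(iv.overlaps(x) for x in b)


class TestClassifyDynamics:
    def test_identity_partition(self):
        x = random_peaks(np.random.default_rng(4), 100)
        dyn = classify_dynamics(x, x)
        assert len(dyn.lost) == len(dyn.gained) == 0
        assert dyn.shared.intervals == x.intervals

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_allpairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        veh = random_peaks(rng, 500, max_pos=300_000, label="veh")
        trt = random_peaks(rng, 500, max_pos=300_000, label="trt")
        dyn = classify_dynamics(veh, trt)
        veh_hits = brute_force_overlaps(veh, trt)
        trt_hits = brute_force_overlaps(trt, veh)
        assert [iv for iv, h in zip(veh, veh_hits) if not h] == dyn.lost.intervals
        assert [iv for iv, h in zip(veh, veh_hits) if h] == dyn.shared.intervals
        assert [iv for iv, h in zip(trt, trt_hits) if not h] == dyn.gained.intervals
        assert len(dyn.lost) + len(dyn.shared) == len(veh)
        assert len(dyn.gained) + len(dyn.shared_treated) == len(trt)


class TestMergeIntervals:
    def test_touching_intervals_merge_at_zero_gap(self):
        ps = PeakSet(
            [GenomicInterval("c", 0, 100, score=1), GenomicInterval("c", 100, 200, score=2)]
        )
        out = merge_intervals(ps, max_gap=0)
        assert len(out) == 1
        assert (out[0].start, out[0].end, out[0].score) == (0, 200, 3.0)

    @pytest.mark.parametrize(
        "gap,max_gap,n_expected", [(9_500, 12_500, 1), (13_500, 12_500, 2)]
    )
    def test_gap_threshold(self, gap, max_gap, n_expected):
        ps = PeakSet(
            [GenomicInterval("c", 0, 500), GenomicInterval("c", 500 + gap, 1000 + gap)]
        )
        assert len(merge_intervals(ps, max_gap=max_gap)) == n_expected

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_matches_connected_components_oracle(self, seed):
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        rng = np.random.default_rng(seed)
        ps = random_peaks(rng, 200, max_pos=100_000, max_len=2_000)
        max_gap = int(rng.integers(0, 3_000))
        out = merge_intervals(ps, max_gap)
        s = np.array([iv.start for iv in ps])
        e = np.array([iv.end for iv in ps])
        chrom = np.array([iv.chrom for iv in ps])
        adj = (
            (chrom[:, None] == chrom[None, :])
            & (s[:, None] - e[None, :] <= max_gap)
            & (s[None, :] - e[:, None] <= max_gap)
        )
        n_comp, lab = connected_components(csr_matrix(adj), directed=False)
        oracle = set()
        for c in range(n_comp):
            idx = np.flatnonzero(lab == c)
            oracle.add(
                (chrom[idx[0]], int(s[idx].min()), int(e[idx].max()))
            )
        assert {(iv.chrom, iv.start, iv.end) for iv in out} == oracle
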