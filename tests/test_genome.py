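import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakbench.genome import (
    GenomeLayout,
    Interval,
    IntervalError,
    PeakSet,
    complement,
    intersect_fraction,
    merge_adjacent,
    read_bed,
    read_chrom_sizes,
    write_bed,
)

from conftest import make_peaks
from oracles import (
    complement_oracle,
    merge_oracle,
    overlap_fraction_oracle,
    random_intervals,
)

CHROM_SIZES = [("c1", 100_000), ("c2", 80_000), ("c3", 50_000)]


class TestReadChromSizes:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("c1\t1000\nc2\t500\n")
        layout = read_chrom_sizes(p)
        assert layout.names == ("c1", "c2")
        assert layout.total_size == 1500

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.sizes"
        p.write_text("")
        with pytest.raises(IntervalError, match="no chromosomes"):
            read_chrom_sizes(p)

    def test_duplicate_name(self, tmp_path):
        p = tmp_path / "dup.sizes"
        p.write_text("c1\t1000\nc1\t900\n")
        with pytest.raises(IntervalError, match="duplicate"):
            read_chrom_sizes(p)

    def test_non_positive_length(self, tmp_path):
        p = tmp_path / "bad.sizes"
        p.write_text("c1\t0\n")
        with pytest.raises(IntervalError, match="non-positive"):
            read_chrom_sizes(p)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.sizes"
        p.write_text("c1\t1000\nc2 nolength\n")
        with pytest.raises(IntervalError, match=":2"):
            read_chrom_sizes(p)


class TestReadBed:
    def test_sorting(self, tmp_path, layout):
        p = tmp_path / "a.bed"
        p.write_text("c1\t100\t200\nc1\t50\t80\n")
        peaks = read_bed(p, layout)
        assert [(iv.start, iv.end) for iv in peaks] == [(50, 80), (100, 200)]
        assert peaks.sorted

    def test_start_ge_end(self, tmp_path, layout):
        p = tmp_path / "b.bed"
        p.write_text("c1\t200\t100\n")
        with pytest.raises(IntervalError, match="start >= end"):
            read_bed(p, layout)

    def test_zero_length_rejected(self, tmp_path, layout):
        p = tmp_path / "z.bed"
        p.write_text("c1\t100\t100\n")
        with pytest.raises(IntervalError, match="start >= end"):
            read_bed(p, layout)

    def test_unknown_chromosome(self, tmp_path, layout):
        p = tmp_path / "c.bed"
        p.write_text("cX\t0\t10\n")
        with pytest.raises(IntervalError, match="unknown chromosome"):
            read_bed(p, layout)

    def test_out_of_bounds(self, tmp_path, layout):
        p = tmp_path / "d.bed"
        p.write_text("c2\t0\t600\n")
        with pytest.raises(IntervalError, match="outside"):
            read_bed(p, layout)

    def test_skips_comments_and_extra_columns(self, tmp_path, layout):
        p = tmp_path / "e.bed"
        p.write_text("# a comment\ntrack name=x\nbrowser position\nc1\t5\t10\tpeak1\t900\n")
        peaks = read_bed(p, layout)
        assert len(peaks) == 1


class TestWriteBed:
    def test_round_trip(self, tmp_path, layout):
        peaks = make_peaks([("c1", 10, 20), ("c2", 5, 400)], layout, label="cond A")
        p = tmp_path / "out.bed"
        write_bed(peaks, p)
        back = read_bed(p, layout)
        assert back == peaks

    def test_empty_set(self, tmp_path, layout):
        peaks = make_peaks([], layout, label="empty")
        p = tmp_path / "out.bed"
        write_bed(peaks, p)
        assert p.read_text() == "# label=empty\n"
        assert len(read_bed(p, layout)) == 0

    def test_large_round_trip_bit_exact(self, tmp_path):
        layout = GenomeLayout(tuple(CHROM_SIZES))
        rng = np.random.default_rng(42)
        ivs = random_intervals(rng, CHROM_SIZES, 10_000)
        peaks = make_peaks(ivs, layout, label="big")
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(peaks, p1)
        write_bed(read_bed(p1, layout), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestMergeAdjacent:
    def test_gap_exactly_150_merges(self, layout):
        peaks = make_peaks([("c1", 100, 200), ("c1", 350, 400)], layout)
        merged = merge_adjacent(peaks, gap=150)
        assert [(iv.start, iv.end) for iv in merged] == [(100, 400)]

    def test_gap_151_does_not_merge(self, layout):
        peaks = make_peaks([("c1", 100, 200), ("c1", 351, 400)], layout)
        merged = merge_adjacent(peaks, gap=150)
        assert len(merged) == 2

    def test_overlapping_always_merge(self, layout):
        peaks = make_peaks([("c1", 100, 300), ("c1", 200, 250)], layout)
        merged = merge_adjacent(peaks, gap=0)
        assert [(iv.start, iv.end) for iv in merged] == [(100, 300)]

    def test_chromosomes_never_merge_across(self, layout):
        peaks = make_peaks([("c1", 900, 1000), ("c2", 0, 100)], layout)
        assert len(merge_adjacent(peaks, gap=1000)) == 2

    def test_unsorted_input_fatal(self):
        peaks = PeakSet(
            intervals=[Interval("c1", 300, 400), Interval("c1", 100, 200)],
            sorted=True,
            chrom_order=("c1",),
        )
        with pytest.raises(IntervalError, match="out of order"):
            merge_adjacent(peaks)
        peaks2 = PeakSet(intervals=[], sorted=False)
        with pytest.raises(IntervalError, match="not sorted"):
            merge_adjacent(peaks2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_transitive_closure_oracle(self, seed):
        layout = GenomeLayout(tuple(CHROM_SIZES))
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, CHROM_SIZES, 200, max_len=500)
        gap = int(rng.integers(0, 300))
        got = merge_adjacent(make_peaks(ivs, layout), gap=gap)
        expected = merge_oracle(ivs, gap)
        assert [(iv.chrom, iv.start, iv.end) for iv in got] == expected

    @given(
        st.lists(
            st.tuples(st.integers(0, 990), st.integers(1, 100)),
            min_size=0,
            max_size=30,
        ),
        st.integers(0, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, raw, gap):
        layout = GenomeLayout((("c1", 2000),))
        ivs = [("c1", s, min(s + w, 2000)) for s, w in raw]
        once = merge_adjacent(make_peaks(ivs, layout), gap=gap)
        twice = merge_adjacent(once, gap=gap)
        assert once.intervals == twice.intervals
        assert len(once) <= len(ivs)


class TestComplement:
    def test_basic(self, layout):
        peaks = make_peaks([("c1", 100, 200), ("c1", 400, 500)], layout)
        comp = complement(peaks, layout)
        c1 = [(iv.start, iv.end) for iv in comp if iv.chrom == "c1"]
        assert c1 == [(0, 100), (200, 400), (500, 1000)]
        # chromosome with no peaks contributes its full span
        c2 = [(iv.start, iv.end) for iv in comp if iv.chrom == "c2"]
        assert c2 == [(0, 500)]

    def test_full_coverage_has_no_complement(self, layout):
        peaks = make_peaks([("c1", 0, 1000)], layout)
        comp = complement(peaks, layout)
        assert all(iv.chrom != "c1" for iv in comp)

    @pytest.mark.parametrize("seed", range(10))
    def test_double_complement_is_normalization(self, seed):
        layout = GenomeLayout(tuple(CHROM_SIZES))
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, CHROM_SIZES, 100, max_len=400)
        peaks = make_peaks(ivs, layout)
        double = complement(complement(peaks, layout), layout)
        norm = merge_adjacent(peaks, gap=0)
        assert double.intervals == norm.intervals

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_bp_oracle(self, seed):
        sizes = [("c1", 3000), ("c2", 2000)]
        layout = GenomeLayout(tuple(sizes))
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, sizes, 40, max_len=300)
        comp = complement(make_peaks(ivs, layout), layout)
        assert [(iv.chrom, iv.start, iv.end) for iv in comp] == complement_oracle(ivs, sizes)

    @pytest.mark.parametrize("seed", range(10))
    def test_coverage_partition(self, seed):
        layout = GenomeLayout(tuple(CHROM_SIZES))
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, CHROM_SIZES, 150, max_len=600)
        peaks = make_peaks(ivs, layout)
        norm = merge_adjacent(peaks, gap=0)
        comp = complement(peaks, layout)
        assert norm.total_bp() + comp.total_bp() == layout.total_size


class TestIntersectFraction:
    def test_exact_boundary_hit(self, layout):
        q = make_peaks([("c1", 0, 100)], layout)
        r = make_peaks([("c1", 80, 300)], layout)
        hits, misses = intersect_fraction(q, r, min_fraction=0.2)
        assert len(hits) == 1 and len(misses) == 0

    def test_one_bp_under_boundary_misses(self, layout):
        q = make_peaks([("c1", 0, 100)], layout)
        r = make_peaks([("c1", 81, 300)], layout)
        hits, misses = intersect_fraction(q, r, min_fraction=0.2)
        assert len(hits) == 0 and len(misses) == 1

    def test_overlap_accumulates_across_reference(self, layout):
        # two refs each give 15 bp; union 30 bp = 30% of the query
        q = make_peaks([("c1", 0, 100)], layout)
        r = make_peaks([("c1", 10, 25), ("c1", 50, 65)], layout)
        hits, _ = intersect_fraction(q, r, min_fraction=0.3)
        assert len(hits) == 1
        hits, _ = intersect_fraction(q, r, min_fraction=0.31)
        assert len(hits) == 0

    def test_query_counted_once(self, layout):
        q = make_peaks([("c1", 0, 100)], layout)
        r = make_peaks([("c1", 0, 40), ("c1", 50, 100)], layout)
        hits, misses = intersect_fraction(q, r, min_fraction=0.2)
        assert len(hits) + len(misses) == 1

    def test_partition_property(self, big_layout):
        rng = np.random.default_rng(7)
        ivs_q = random_intervals(rng, CHROM_SIZES, 300)
        ivs_r = random_intervals(rng, CHROM_SIZES, 300)
        q = make_peaks(ivs_q, big_layout)
        r = make_peaks(ivs_r, big_layout)
        hits, misses = intersect_fraction(q, r, min_fraction=0.2)
        assert sorted(hits.intervals + misses.intervals) == sorted(q.intervals)

    def test_min_fraction_validation(self, layout):
        q = make_peaks([("c1", 0, 100)], layout)
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(IntervalError, match="min_fraction"):
                intersect_fraction(q, q, min_fraction=bad)

    def test_full_containment_at_fraction_one(self, layout):
        q = make_peaks([("c1", 10, 20), ("c1", 30, 50)], layout)
        r = make_peaks([("c1", 10, 20), ("c1", 30, 49)], layout)
        hits, misses = intersect_fraction(q, r, min_fraction=1.0)
        assert [(iv.start, iv.end) for iv in hits] == [(10, 20)]

    def test_tiny_fraction_means_any_overlap(self, layout):
        q = make_peaks([("c1", 0, 1000)], layout)
        r = make_peaks([("c1", 999, 1000)], layout)
        hits, _ = intersect_fraction(q, r, min_fraction=1e-9)
        assert len(hits) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle(self, seed):
        layout = GenomeLayout(tuple(CHROM_SIZES))
        rng = np.random.default_rng(seed)
        ivs_q = random_intervals(rng, CHROM_SIZES, 500)
        ivs_r = random_intervals(rng, CHROM_SIZES, 500)
        q = make_peaks(ivs_q, layout)
        r = make_peaks(ivs_r, layout)
        frac = float(rng.choice([0.1, 0.2, 0.5, 0.9]))
        hits, _ = intersect_fraction(q, r, min_fraction=frac)
        hit_set = {(iv.chrom, iv.start, iv.end) for iv in hits}
        triples = [(iv.chrom, iv.start, iv.end) for iv in q.intervals]
        oracle = overlap_fraction_oracle(triples, ivs_r, CHROM_SIZES)
        for triple, f in zip(triples, oracle):
            assert (f >= frac) == (triple in hit_set), (triple, f, frac)

    def test_reciprocal_stricter(self, layout):
        # query 100 bp fully inside a 1000 bp reference: plain hit at f=0.2,
        # reciprocal miss (only 10% of the reference interval)
        q = make_peaks([("c1", 100, 200)], layout)
        r = make_peaks([("c1", 0, 1000)], layout)
        hits, _ = intersect_fraction(q, r, min_fraction=0.2)
        assert len(hits) == 1
        hits_r, _ = intersect_fraction(q, r, min_fraction=0.2, reciprocal=True)
        assert len(hits_r) == 0


class TestLayoutValidation:
    def test_duplicate_names(self):
        with pytest.raises(IntervalError, match="duplicate"):
            GenomeLayout((("c1", 10), ("c1", 20)))

    def test_positive_lengths(self):
        with pytest.raises(IntervalError):
            GenomeLayout((("c1", 0),))

    def test_interval_validation(self):
        with pytest.raises(IntervalError):
            Interval("c1", 10, 10)
        with pytest.raises(IntervalError):
            Interval("c1", -1, 10)
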