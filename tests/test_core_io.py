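"""Interval plumbing, format parsers and the shared statistical primitives."""

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from epicoherence.core_io import (
    BinnedTrack,
    GenomicInterval,
    bh_adjust,
    bin_genome,
    count_in_bins,
    cpm_normalize,
    fisher_exact_2x2,
    overlap_select,
    read_bed,
    read_methylation_table,
    write_bed,
)


class TestIntervalsAndBed:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 100)
        assert len(GenomicInterval("chr1", 100, 200)) == 100

    def test_read_bed_basics(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr2\t0\t50\tname\t0\t-\n")
        ivs = read_bed(p)
        assert ivs[0] == GenomicInterval("chr1", 100, 200)
        assert ivs[1].strand == "-"

    def test_read_bed_errors_name_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t200\t100\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(p)

    def test_read_bed_empty(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_bed(p) == []

    def test_bed_round_trip(self, tmp_path):
        p1, p2 = tmp_path / "x.bed", tmp_path / "y.bed"
        p1.write_text("chr1\t100\t200\nchr1\t500\t900\nchr2\t0\t7\n")
        write_bed(read_bed(p1), p2)
        assert p1.read_text() == p2.read_text()


class TestMethylationTable:
    def test_plain_dialect(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chr1\t1000\t1001\t9\t1\nchr1\t2000\t2001\t0\t0\n")
        df = read_methylation_table(p)
        level = df["meth_reads"] / (df["meth_reads"] + df["unmeth_reads"])
        assert level.iloc[0] == pytest.approx(0.9)
        assert not df["covered"].iloc[1]

    def test_percent_dialect_equivalence(self, tmp_path):
        plain = tmp_path / "plain.tsv"
        plain.write_text("chr1\t1000\t1001\t9\t1\n")
        pct = tmp_path / "pct.tsv"
        pct.write_text("chr1\t1000\t1001\t90.0\t9\t1\n")
        a = read_methylation_table(plain)
        b = read_methylation_table(pct)
        assert (a[["meth_reads", "unmeth_reads"]].values == b[["meth_reads", "unmeth_reads"]].values).all()

    def test_negative_counts_rejected(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text("chr1\t1000\t1001\t-1\t5\n")
        with pytest.raises(ValueError):
            read_methylation_table(p)


class TestBinning:
    @pytest.mark.parametrize(
        "sizes, bin_size, expected",
        [
            ({"c": 450}, 200, [(0, 200), (200, 400), (400, 450)]),
            ({"c": 400}, 200, [(0, 200), (200, 400)]),
            ({"a": 400, "b": 200}, 200, [(0, 200), (200, 400), (0, 200)]),
        ],
    )
    def test_bin_genome(self, sizes, bin_size, expected):
        bins = bin_genome(sizes, bin_size)
        assert [(b.start, b.end) for b in bins] == expected

    @pytest.mark.parametrize(
        "strand, shift, target_bin",
        [("+", 100, 1), ("-", 100, 0), ("+", 0, 0)],
    )
    def test_shift_rule(self, strand, shift, target_bin):
        # 5' position 150: + shift lands at 250 (bin 1), - shift at 50 (bin 0)
        track = count_in_bins([("c", 150, strand)], {"c": 600}, 200, shift_bp=shift)
        assert track.counts[target_bin] == 1 and track.counts.sum() == 1

    def test_read_conservation_any_shift(self, rng):
        sizes = {"c1": 10_000, "c2": 5_000}
        reads = [
            (rng.choice(["c1", "c2", "unknown"]), int(rng.integers(0, 10_000)),
             rng.choice(["+", "-", "."]))
            for _ in range(500)
        ]
        for shift in (0, 100, 333):
            track = count_in_bins(reads, sizes, 200, shift_bp=shift)
            skipped = len(reads) - track.counts.sum()
            assert track.counts.sum() + skipped == 500
            assert skipped >= sum(1 for r in reads if r[0] == "unknown")

    def test_cpm(self):
        t = BinnedTrack("s", "m", 200, np.array([2, 0]), int(1e6))
        assert cpm_normalize(t).tolist() == [2.0, 0.0]
        t5 = BinnedTrack("s", "m", 200, np.array([5]), int(5e6))
        assert cpm_normalize(t5).tolist() == [1.0]
        with pytest.raises(ValueError):
            cpm_normalize(BinnedTrack("s", "m", 200, np.array([0]), 0))


class TestOverlapSelect:
    def test_boundary_fraction(self):
        q = [GenomicInterval("c", 0, 100)]
        ref = [GenomicInterval("c", 50, 200)]
        assert overlap_select(q, ref, 0.5)[0]
        assert not overlap_select(q, ref, 0.51)[0]

    def test_disjoint_and_split_overlap(self):
        q = [GenomicInterval("c", 0, 100), GenomicInterval("c", 1000, 1100)]
        ref = [GenomicInterval("c", 0, 30), GenomicInterval("c", 60, 90)]
        got = overlap_select(q, ref, 0.5)
        assert got.tolist() == [True, False]  # 30 + 30 = 60 >= 50


def _bh_oracle(p):
    """Independent step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        q[i] = running
    return q


class TestBHAdjust:
    def test_hand_enumerated_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_degenerate(self):
        assert bh_adjust([0.5]).tolist() == [0.5]
        assert bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_against_independent_step_up_oracle(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 51))
            p = rng.random(m)
            np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)


class TestFisherExact:
    def test_spec_examples(self):
        assert fisher_exact_2x2(0, 10, 10, 0) == pytest.approx(1.082508822446903e-05, rel=1e-9)
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)
        assert fisher_exact_2x2(1, 0, 0, 0) == 1.0  # degenerate margin

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 80, size=4)
            ours = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            ref = scipy_fisher([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_exhaustive_enumeration_small_margins(self):
        """Exact integer-arithmetic enumeration for all tables with row
        margins up to 12 (the full <=30 sweep lives in the acceptance suite)."""
        for r1 in range(13):
            for r2 in range(13):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        expected = _fisher_oracle(a, r1 - a, c, r2 - c)
                        got = fisher_exact_2x2(a, r1 - a, c, r2 - c)
                        assert got == pytest.approx(expected, abs=1e-10), (a, r1 - a, c, r2 - c)


def _fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by integer enumeration over the support."""
    r1, r2, k = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or k == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, k - r2), min(k, r1)
    nums = [math.comb(r1, x) * math.comb(r2, k - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    return sum(n for n in nums if n <= obs) / math.comb(r1 + r2, k)
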