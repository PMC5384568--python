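"""Evaluation machinery: reference mapping, contig statistics, gap/coverage/
repeat interval arithmetic, read-length histograms — each against an
independent oracle."""
from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from twolayer.evaluate import (
    AlignmentRecord,
    contig_stats,
    coverage_by_min_length,
    duplicated_fraction,
    evaluate_assembly,
    gap_analysis,
    map_contigs_to_reference,
    read_length_histogram,
    repeat_resolution,
)
from twolayer.layer1 import Contig
from twolayer.simdata import Genome, RepeatAnnotation


def bio_rc(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mk_genome(seq: str, repeats=()) -> Genome:
    return Genome(id="ref", sequence=seq, repeats=RepeatAnnotation(tuple(repeats)))


def oracle_n50(lengths: list[int]) -> int:
    """Direct evaluation of the definition: largest L with sum of lengths
    >= L at least half the total."""
    total = sum(lengths)
    best = 0
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) * 2 >= total:
            best = max(best, L)
    return best


class TestMapContigsToReference:
    def test_exact_substring_maps_with_identity_one(self, rng):
        ref = mk_genome(random_seq(rng, 2000))
        contig = Contig("c0", ref.sequence[300:900])
        records = map_contigs_to_reference([contig], ref)
        assert len(records) == 1
        rec = records[0]
        assert (rec.ref_start, rec.ref_end, rec.strand, rec.identity) == (300, 900, "+", 1.0)

    def test_unrelated_contig_yields_no_records(self, rng):
        ref = mk_genome(random_seq(rng, 2000))
        contig = Contig("c0", random_seq(rng, 500))
        assert map_contigs_to_reference([contig], ref) == []

    def test_reverse_complement_maps_on_minus_strand(self, rng):
        ref = mk_genome(random_seq(rng, 2000))
        contig = Contig("c0", bio_rc(ref.sequence[500:1200]))
        records = map_contigs_to_reference([contig], ref)
        assert len(records) == 1
        rec = records[0]
        assert (rec.ref_start, rec.ref_end, rec.strand) == (500, 1200, "-")

    def test_split_alignment_across_junction(self, rng):
        # a contig stitched from two distant reference windows maps as
        # two non-overlapping parts
        ref = mk_genome(random_seq(rng, 3000))
        contig = Contig("c0", ref.sequence[100:600] + ref.sequence[2000:2500])
        records = map_contigs_to_reference([contig], ref)
        intervals = sorted((r.ref_start, r.ref_end) for r in records)
        assert intervals == [(100, 600), (2000, 2500)]


class TestContigStats:
    def test_small_multiset_example(self):
        contigs = [Contig(f"c{i}", "A" * n) for i, n in enumerate([5, 4, 3, 2, 1])]
        count, n50_val, mean, longest = contig_stats(contigs, min_length=0)
        assert (count, n50_val, mean, longest) == (5, 4, 3.0, 5)
        assert n50_val == oracle_n50([5, 4, 3, 2, 1])

    def test_single_contig(self):
        count, n50_val, mean, longest = contig_stats([Contig("c", "A" * 1000)])
        assert (count, n50_val, mean, longest) == (1, 1000, 1000.0, 1000)

    def test_length_threshold_arithmetic(self):
        contigs = [Contig(f"c{i}", "A" * n) for i, n in enumerate([999, 1000, 1001])]
        count, *_ = contig_stats(contigs, min_length=1000)
        assert count == 2

    def test_empty_set_reports_zeros(self):
        assert contig_stats([], min_length=0) == (0, 0, 0.0, 0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.integers(1, 5000), min_size=1, max_size=30))
    def test_n50_matches_definition_oracle(self, lengths):
        contigs = [Contig(f"c{i}", "A" * n) for i, n in enumerate(lengths)]
        _, n50_val, mean, longest = contig_stats(contigs, min_length=0)
        assert n50_val == oracle_n50(lengths)
        assert longest == max(lengths)
        assert mean == pytest.approx(float(np.mean(lengths)))
        assert n50_val <= longest


def _records(intervals, contig_length=5000):
    return [
        AlignmentRecord(f"c{i}", "ref", s, e, "+", 1.0, e - s, contig_length)
        for i, (s, e) in enumerate(intervals)
    ]


class TestGapAnalysis:
    def test_single_interior_gap(self, rng):
        ref = mk_genome(random_seq(rng, 100))
        n_gaps, gaps, frac = gap_analysis(_records([(0, 50), (60, 100)]), ref)
        assert (n_gaps, gaps, frac) == (1, [(50, 60)], 0.9)

    def test_full_tiling_has_no_gaps(self, rng):
        ref = mk_genome(random_seq(rng, 100))
        n_gaps, gaps, frac = gap_analysis(_records([(0, 70), (50, 100)]), ref)
        assert (n_gaps, gaps, frac) == (0, [], 1.0)

    def test_matches_perbase_boolean_oracle(self, rng):
        length = 3000
        ref = mk_genome(random_seq(rng, length))
        intervals = []
        for _ in range(200):
            s = int(rng.integers(0, length - 1))
            e = int(rng.integers(s + 1, min(s + 120, length) + 1))
            intervals.append((s, e))
        n_gaps, gaps, frac = gap_analysis(_records(intervals), ref)
        covered = np.zeros(length, dtype=bool)
        for s, e in intervals:
            covered[s:e] = True
        assert frac == covered.sum() / length
        # gaps = maximal runs of uncovered positions
        runs = []
        in_run = False
        for i, c in enumerate(covered):
            if not c and not in_run:
                runs.append([i, i + 1])
                in_run = True
            elif not c:
                runs[-1][1] = i + 1
            else:
                in_run = False
        assert gaps == [tuple(r) for r in runs]
        assert n_gaps == len(runs)


class TestCoverageCurve:
    def test_constant_curve_for_single_long_contig(self, rng):
        ref = mk_genome(random_seq(rng, 100_000))
        recs = [AlignmentRecord("c", "ref", 0, 10_000, "+", 1.0, 10_000, 10_000)]
        curve = coverage_by_min_length(recs, ref, thresholds=list(range(1000, 10001, 500)))
        assert all(frac == pytest.approx(0.10) for _t, frac in curve)

    def test_threshold_above_longest_contig_drops_to_zero(self, rng):
        ref = mk_genome(random_seq(rng, 10_000))
        recs = [AlignmentRecord("c", "ref", 0, 5000, "+", 1.0, 5000, 5000)]
        curve = coverage_by_min_length(recs, ref, thresholds=[1000, 6000])
        assert curve == [(1000, 0.5), (6000, 0.0)]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 900), st.integers(100, 3000)), max_size=15))
    def test_curve_is_non_increasing(self, placements):
        ref = mk_genome("A" * 1000)
        recs = [
            AlignmentRecord(f"c{i}", "ref", s, min(1000, s + min(length, 1000)),
                            "+", 1.0, 100, length)
            for i, (s, length) in enumerate(placements)
        ]
        curve = coverage_by_min_length(recs, ref, thresholds=[0, 500, 1000, 2000, 3000])
        fracs = [f for _t, f in curve]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        # value at threshold 0 equals the plain covered fraction
        assert fracs[0] == gap_analysis(recs, ref)[2]


class TestRepeatResolution:
    def test_half_overlapping_gap(self):
        repeats = RepeatAnnotation(((10, 20, "rep0"),))
        assert repeat_resolution([(15, 25)], repeats) == 0.5

    def test_no_gaps_fully_resolved(self):
        repeats = RepeatAnnotation(((10, 20, "rep0"),))
        assert repeat_resolution([], repeats) == 0.0

    def test_no_repeat_bases_is_not_applicable(self):
        assert repeat_resolution([(0, 5)], RepeatAnnotation()) is None

    def test_matches_perbase_oracle(self, rng):
        length = 2000
        repeats = []
        pos = 0
        for i in range(8):
            start = pos + int(rng.integers(20, 120))
            end = start + int(rng.integers(10, 90))
            repeats.append((start, end, f"rep{i}"))
            pos = end
        gaps = []
        for _ in range(30):
            s = int(rng.integers(0, length - 1))
            gaps.append((s, s + int(rng.integers(1, 80))))
        repeat_mask = np.zeros(length + 200, dtype=bool)
        for s, e, _f in repeats:
            repeat_mask[s:e] = True
        gap_mask = np.zeros(length + 200, dtype=bool)
        for s, e in gaps:
            gap_mask[s:e] = True
        expected = (repeat_mask & gap_mask).sum() / repeat_mask.sum()
        result = repeat_resolution(gaps, RepeatAnnotation(tuple(repeats)))
        assert result == pytest.approx(expected)


class TestHistogramAndReport:
    def test_histogram_counts_lengths(self):
        reads = [Contig(f"r{i}", "A" * 100) for i in range(3)]
        assert read_length_histogram(reads) == {100: 3}

    def test_empty_histogram(self):
        assert read_length_histogram([]) == {}

    def test_duplicated_fraction_counts_multicovered_bases(self, rng):
        ref = mk_genome(random_seq(rng, 100))
        recs = _records([(0, 60), (40, 100)])
        assert duplicated_fraction(recs, ref) == pytest.approx(0.2)

    def test_full_report_invariants_on_simulated_contigs(self, rng):
        ref_seq = random_seq(rng, 12_000)
        ref = mk_genome(ref_seq, repeats=[(2000, 2100, "rep0")])
        contigs = [
            Contig("c0", ref_seq[0:4000]),
            Contig("c1", bio_rc(ref_seq[3800:9000])),
            Contig("c2", ref_seq[9500:11_000]),
        ]
        report = evaluate_assembly("test", contigs, ref, min_length=1000,
                                   thresholds=[1000, 2000, 4000])
        assert report.n50 <= report.longest_contig
        fracs = [f for _t, f in report.coverage_curve]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert report.n_gaps == 2  # [9000, 9500) and the [11000, 12000) tail
        assert report.genome_covered_fraction == pytest.approx(10_500 / 12_000)
        assert report.repeat_unresolved_fraction == 0.0
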