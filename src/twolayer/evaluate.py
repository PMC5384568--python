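"""Assembly evaluation against a known reference.

Metrics follow the usual assembly-comparison conventions: contig counts and
N50/mean/longest over contigs above a length cutoff, the number and extent
of reference gaps left after mapping the contigs, the fraction of the
reference covered when only contigs above increasing length thresholds are
kept (a coverage-by-minimum-contig-length curve), the fraction of annotated
repeat bases left unresolved, and read-length histograms.

Contig-to-reference mapping is a deterministic seed-chain-extend aligner:
exact 31-mer seeds grouped by diagonal, exact match runs merged while the
combined identity stays above the threshold, split (multi-part) alignments
allowed, non-overlapping on the contig.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from .layer1 import Contig
from .preprocess import ReadSet
from .seq import n50 as _n50
from .seq import revcomp, seq_to_array
from .simdata import Genome, RepeatAnnotation

MAP_SEED_LENGTH = 31
DEFAULT_THRESHOLDS = tuple(range(1000, 10001, 500))


@dataclass
class AlignmentRecord:
    contig_id: str
    reference_id: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    contig_span: int
    contig_length: int


@dataclass
class AssemblyReport:
    name: str
    n_contigs: int
    n50: int
    mean_contig_length: float
    longest_contig: int
    n_gaps: int
    genome_covered_fraction: float
    duplicated_fraction: float
    coverage_curve: list[tuple[int, float]] = field(default_factory=list)
    repeat_unresolved_fraction: float | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_contigs": self.n_contigs,
            "n50": self.n50,
            "mean_contig_length": round(self.mean_contig_length, 1),
            "longest_contig": self.longest_contig,
            "n_gaps": self.n_gaps,
            "genome_covered_fraction": round(self.genome_covered_fraction, 6),
            "duplicated_fraction": round(self.duplicated_fraction, 6),
            "coverage_curve": [[t, round(f, 6)] for t, f in self.coverage_curve],
            "repeat_unresolved_fraction": (
                None
                if self.repeat_unresolved_fraction is None
                else round(self.repeat_unresolved_fraction, 6)
            ),
        }


# ---------------------------------------------------------------------------
# Contig-to-reference mapping
# ---------------------------------------------------------------------------

def _match_runs(equal: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open intervals."""
    if equal.size == 0:
        return []
    padded = np.concatenate(([False], equal, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def map_contigs_to_reference(
    contigs: Sequence[Contig],
    reference: Genome,
    min_identity: float = 0.9,
    seed_len: int = MAP_SEED_LENGTH,
    min_alignment_length: int = MAP_SEED_LENGTH,
) -> list[AlignmentRecord]:
    """Local alignments of each contig against the reference, both strands.

    Split alignments are permitted; the parts reported for one contig are
    non-overlapping on the contig, longest first.
    """
    if len(reference) == 0:
        raise ValueError("reference must be non-empty")
    ref = reference.sequence
    rarr = seq_to_array(ref)
    index: dict[str, list[int]] = {}
    for pos in range(len(ref) - seed_len + 1):
        index.setdefault(ref[pos:pos + seed_len], []).append(pos)

    records: list[AlignmentRecord] = []
    for contig in contigs:
        candidates: list[tuple[int, int, int, float, str]] = []
        # (span, contig_start, ref_start, identity, strand)
        for strand in "+-":
            cs = contig.sequence if strand == "+" else revcomp(contig.sequence)
            n = len(cs)
            if n < seed_len:
                continue
            carr = seq_to_array(cs)
            stride = max(1, seed_len // 2)
            offsets = list(range(0, n - seed_len + 1, stride))
            if offsets[-1] != n - seed_len:
                offsets.append(n - seed_len)
            diagonals = set()
            for off in offsets:
                for pos in index.get(cs[off:off + seed_len], ()):
                    diagonals.add(pos - off)
            for diag in sorted(diagonals):
                c0 = max(0, -diag)
                c1 = min(n, len(ref) - diag)
                if c1 - c0 < seed_len:
                    continue
                equal = carr[c0:c1] == rarr[c0 + diag:c1 + diag]
                runs = [
                    (s + c0, e + c0)
                    for s, e in _match_runs(equal)
                    if e - s >= seed_len
                ]
                # chain runs on this diagonal while identity stays admissible
                merged: list[tuple[int, int, int]] = []  # (start, end, matches)
                for s, e in runs:
                    if merged:
                        ps, pe, pm = merged[-1]
                        span = e - ps
                        matches = pm + (e - s)
                        if matches / span >= min_identity:
                            merged[-1] = (ps, e, matches)
                            continue
                    merged.append((s, e, e - s))
                for s, e, matches in merged:
                    if e - s >= min_alignment_length:
                        candidates.append(
                            (e - s, s, s + diag, matches / (e - s), strand)
                        )
        # keep non-overlapping (on the contig) candidates, longest first
        candidates.sort(key=lambda c: (-c[0], c[4], c[1], c[2]))
        taken: list[tuple[int, int]] = []
        n = len(contig.sequence)
        for span, cstart, rstart, identity, strand in candidates:
            if strand == "+":
                a, b = cstart, cstart + span
            else:  # convert back to forward-contig coordinates
                a, b = n - (cstart + span), n - cstart
            if any(a < te and ts < b for ts, te in taken):
                continue
            taken.append((a, b))
            records.append(
                AlignmentRecord(
                    contig_id=contig.id,
                    reference_id=reference.id,
                    ref_start=rstart,
                    ref_end=rstart + span,
                    strand=strand,
                    identity=identity,
                    contig_span=span,
                    contig_length=n,
                )
            )
    records.sort(key=lambda r: (r.ref_start, r.ref_end, r.contig_id))
    return records


# ---------------------------------------------------------------------------
# Interval arithmetic on the reference
# ---------------------------------------------------------------------------

def _union(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def gap_analysis(
    alignments: Sequence[AlignmentRecord], reference: Genome
) -> tuple[int, list[tuple[int, int]], float]:
    """(gap count, gap intervals, covered fraction) from the union of
    aligned reference intervals. Every maximal uncovered interval of length
    >= 1 counts as one gap."""
    length = len(reference)
    covered = _union((r.ref_start, r.ref_end) for r in alignments)
    gaps: list[tuple[int, int]] = []
    prev = 0
    for start, end in covered:
        if start > prev:
            gaps.append((prev, start))
        prev = max(prev, end)
    if prev < length:
        gaps.append((prev, length))
    covered_len = sum(e - s for s, e in covered)
    return len(gaps), gaps, covered_len / length


def duplicated_fraction(
    alignments: Sequence[AlignmentRecord], reference: Genome
) -> float:
    """Fraction of the reference covered by more than one alignment."""
    events: list[tuple[int, int]] = []
    for r in alignments:
        events.append((r.ref_start, 1))
        events.append((r.ref_end, -1))
    events.sort()
    depth = 0
    prev = 0
    dup = 0
    for pos, delta in events:
        if depth > 1:
            dup += pos - prev
        prev = pos
        depth += delta
    return dup / len(reference)


def coverage_by_min_length(
    alignments: Sequence[AlignmentRecord],
    reference: Genome,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> list[tuple[int, float]]:
    """Covered fraction using only contigs of length >= t, per threshold."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    curve = []
    for t in thresholds:
        kept = [r for r in alignments if r.contig_length >= t]
        _, _, frac = gap_analysis(kept, reference)
        curve.append((t, frac))
    return curve


def repeat_resolution(
    gaps: Sequence[tuple[int, int]], repeats: RepeatAnnotation
) -> float | None:
    """Unresolved fraction: gap bases inside annotated repeats over total
    annotated repeat bases. ``None`` when there are no repeat bases."""
    total = repeats.total_bases()
    if total == 0:
        return None
    merged_gaps = _union(gaps)
    unresolved = 0
    for rstart, rend, _fam in repeats.intervals:
        for gstart, gend in merged_gaps:
            lo, hi = max(rstart, gstart), min(rend, gend)
            if hi > lo:
                unresolved += hi - lo
    return unresolved / total


def read_length_histogram(reads: Union[ReadSet, Iterable]) -> dict[int, int]:
    if isinstance(reads, ReadSet):
        lengths = [len(r.sequence) for r in reads.reads]
    else:
        lengths = [len(getattr(r, "sequence", r)) for r in reads]
    return dict(Counter(lengths))


# ---------------------------------------------------------------------------
# Contig statistics and the full report
# ---------------------------------------------------------------------------

def contig_stats(
    contigs: Sequence[Contig], min_length: int = 0
) -> tuple[int, int, float, int]:
    """(count, N50, mean, longest) over contigs of length >= min_length.

    N50 is the largest L such that contigs of length >= L hold at least
    half the total length of the filtered set. An empty set reports zeros.
    """
    lengths = [len(c.sequence) for c in contigs if len(c.sequence) >= min_length]
    if not lengths:
        return 0, 0, 0.0, 0
    return len(lengths), _n50(lengths), sum(lengths) / len(lengths), max(lengths)


def evaluate_assembly(
    name: str,
    contigs: Sequence[Contig],
    reference: Genome,
    min_length: int = 1000,
    min_identity: float = 0.9,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> AssemblyReport:
    """Map contigs >= min_length to the reference and bundle all metrics."""
    kept = [c for c in contigs if len(c.sequence) >= min_length]
    count, n50_val, mean, longest = contig_stats(kept)
    alignments = map_contigs_to_reference(kept, reference, min_identity)
    n_gaps, gaps, covered = gap_analysis(alignments, reference)
    return AssemblyReport(
        name=name,
        n_contigs=count,
        n50=n50_val,
        mean_contig_length=mean,
        longest_contig=longest,
        n_gaps=n_gaps,
        genome_covered_fraction=covered,
        duplicated_fraction=duplicated_fraction(alignments, reference),
        coverage_curve=coverage_by_min_length(alignments, reference, thresholds),
        repeat_unresolved_fraction=repeat_resolution(gaps, reference.repeats),
    )
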