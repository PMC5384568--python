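"""Read preprocessing: adapter clipping, quality trimming, pair merging.

Short-insert libraries sequence through the fragment into the adapter, and
forward/reverse reads of the same fragment usually overlap. Preprocessing
therefore (1) clips adapter read-through, (2) trims low-quality 3' tails and
(3) optionally collapses each overlapping pair into a single full-fragment
read. Three downstream treatments are produced:

``MERGED``
    merged pairs plus whatever could not be merged, as single-end reads;
``PAIRED``
    adapter-clipped/trimmed complete pairs only (orphans dropped);
``COMBINED``
    every surviving read, orphans included, as single-end reads with
    globally unique identifiers.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .seq import revcomp, seq_to_array

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


class Mate(enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    MERGED = "merged"
    SINGLE = "single"


class Mode(enum.Enum):
    MERGED = "merged"
    PAIRED = "paired"
    COMBINED = "combined"


@dataclass
class Read:
    """A sequencing read: sequence plus per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int]
    mate: Mate = Mate.SINGLE

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """A collection of reads tagged with its preprocessing mode."""

    mode: Mode
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.reads]


# ---------------------------------------------------------------------------
# Adapter clipping
# ---------------------------------------------------------------------------

def clip_adapter(
    read: Read,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 3,
    max_mismatch_frac: float = 0.1,
) -> Read:
    """Remove adapter read-through from the 3' end of a read.

    The leftmost position where the remainder of the read matches a prefix of
    the adapter (match length >= ``min_overlap``, mismatch fraction <=
    ``max_mismatch_frac``) is located; that suffix — an internal full adapter
    occurrence or a terminal partial one — and everything 3' of it is removed.
    A read with no admissible match is returned unchanged.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = read.sequence
    n, a = len(seq), len(adapter)
    if n < min_overlap or a == 0:
        return read
    sarr = seq_to_array(seq)
    aarr = seq_to_array(adapter)
    for i in range(0, n - min_overlap + 1):
        ov = min(n - i, a)
        if ov < min_overlap:
            break
        mism = int(np.count_nonzero(sarr[i:i + ov] != aarr[:ov]))
        if mism <= int(max_mismatch_frac * ov):
            return replace(read, sequence=seq[:i], qualities=read.qualities[:i])
    return read


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------

def quality_trim(
    read: Read, q_threshold: int = 20, min_length: int = 25
) -> Optional[Read]:
    """Trim 3'-terminal bases below ``q_threshold``; discard short survivors.

    Returns ``None`` (DISCARD) when fewer than ``min_length`` bases remain.
    """
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    end = len(read)
    while end > 0 and read.qualities[end - 1] < q_threshold:
        end -= 1
    if end < min_length:
        return None
    if end == len(read):
        return read
    return replace(read, sequence=read.sequence[:end], qualities=read.qualities[:end])


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------

def merge_pair(
    fwd: Read,
    rev: Read,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.05,
) -> Optional[Read]:
    """Collapse an overlapping forward/reverse pair into one read.

    The reverse read is reverse-complemented and slid against the forward
    read over every relative shift, including negative shifts where the
    reverse-complemented read starts *before* the forward read — the
    read-through geometry of inserts shorter than the read length, whose
    overhangs are adapter remnants and are trimmed away. The placement with
    the most matching bases (mismatch fraction <= ``max_mismatch_frac``,
    overlap >= ``min_overlap``; ties go to the longer overlap) wins. Within
    the overlap, agreeing bases take the larger quality; disagreeing bases
    take the higher-quality base with quality ``max(|q1-q2|, 2)`` (forward
    base on a quality tie). Returns ``None`` (UNMERGED) when no admissible
    placement exists.
    """
    rseq = revcomp(rev.sequence)
    rquals = rev.qualities[::-1]
    lf, lr = len(fwd), len(rseq)
    if lf == 0 or lr == 0:
        return None
    farr = seq_to_array(fwd.sequence)
    rarr = seq_to_array(rseq)
    # shift d: start of the reverse-complemented read on forward coordinates
    best: tuple[int, int, int] | None = None  # (matches, overlap, d)
    for d in range(-(lr - min_overlap), lf - min_overlap + 1):
        f0 = max(0, d)
        f1 = min(lf, lr + d)
        ov = f1 - f0
        if ov < min_overlap:
            continue
        mism = int(np.count_nonzero(farr[f0:f1] != rarr[f0 - d:f1 - d]))
        if mism <= int(max_mismatch_frac * ov):
            cand = (ov - mism, ov, d)
            if best is None or cand >= best:
                best = cand
    if best is None:
        return None
    _, ov, d = best
    f0 = max(0, d)
    f1 = min(lf, lr + d)
    if d >= 0:
        seq = list(fwd.sequence[:f0])
        quals = list(fwd.qualities[:f0])
    else:  # read-through: left overhang of the reverse read is adapter
        seq, quals = [], []
    for j in range(f0, f1):
        fb, fq = fwd.sequence[j], fwd.qualities[j]
        rb, rq = rseq[j - d], rquals[j - d]
        if fb == rb:
            seq.append(fb)
            quals.append(max(fq, rq))
        elif fq >= rq:
            seq.append(fb)
            quals.append(max(fq - rq, 2))
        else:
            seq.append(rb)
            quals.append(max(rq - fq, 2))
    # the reverse read's 5' end marks the fragment's 3' terminus: keep its
    # tail, drop any forward-read bases past it (adapter read-through)
    seq.extend(rseq[f1 - d:])
    quals.extend(rquals[f1 - d:])
    base_id = fwd.id[:-2] if fwd.id.endswith(("/1", "/2")) else fwd.id
    return Read(base_id, "".join(seq), quals, Mate.MERGED)


# ---------------------------------------------------------------------------
# The three preprocessing treatments
# ---------------------------------------------------------------------------

def prepare_modes(
    pairs: Sequence[tuple[Optional[Read], Optional[Read]]],
    singletons: Sequence[Read] = (),
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.05,
) -> tuple[ReadSet, ReadSet, ReadSet]:
    """Build the MERGED / PAIRED / COMBINED read sets.

    ``pairs`` holds already clipped/trimmed mates; a ``None`` member marks a
    mate discarded during trimming (its partner is an orphan). Orphans are
    dropped from PAIRED but kept in MERGED and COMBINED.
    """
    merged_set = ReadSet(Mode.MERGED)
    paired_set = ReadSet(Mode.PAIRED)
    combined_set = ReadSet(Mode.COMBINED)

    def as_single(read: Read, new_id: str) -> Read:
        return replace(read, id=new_id, mate=Mate.SINGLE)

    serial = 0
    for fwd, rev in pairs:
        if fwd is not None and rev is not None:
            paired_set.reads.append(fwd)
            paired_set.reads.append(rev)
            merged = merge_pair(fwd, rev, min_overlap, max_mismatch_frac)
            if merged is not None:
                merged_set.reads.append(merged)
            else:
                merged_set.reads.append(as_single(fwd, f"{fwd.id}|u1"))
                merged_set.reads.append(as_single(rev, f"{rev.id}|u2"))
            combined_set.reads.append(as_single(fwd, f"c{serial}|{fwd.id}"))
            serial += 1
            combined_set.reads.append(as_single(rev, f"c{serial}|{rev.id}"))
            serial += 1
        else:
            orphan = fwd if fwd is not None else rev
            if orphan is None:
                continue
            merged_set.reads.append(as_single(orphan, f"{orphan.id}|o"))
            combined_set.reads.append(as_single(orphan, f"c{serial}|{orphan.id}"))
            serial += 1
    for read in singletons:
        merged_set.reads.append(as_single(read, f"{read.id}|s"))
        combined_set.reads.append(as_single(read, f"c{serial}|{read.id}"))
        serial += 1

    ids = [r.id for r in combined_set.reads]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate read ids in COMBINED read set")
    return merged_set, paired_set, combined_set


@dataclass
class PreprocessStats:
    pairs_in: int = 0
    singletons_in: int = 0
    clipped: int = 0
    discarded: int = 0
    merged: int = 0
    orphans: int = 0


def preprocess_pairs(
    pairs: Sequence[tuple[Read, Read]],
    singletons: Sequence[Read] = (),
    adapter: str = DEFAULT_ADAPTER,
    clip_min_overlap: int = 3,
    clip_max_mismatch_frac: float = 0.1,
    q_threshold: int = 20,
    min_length: int = 25,
    merge_min_overlap: int = 10,
    merge_max_mismatch_frac: float = 0.05,
) -> tuple[ReadSet, ReadSet, ReadSet, PreprocessStats]:
    """Clip, trim and build all three treatments from raw pairs."""
    stats = PreprocessStats(pairs_in=len(pairs), singletons_in=len(singletons))

    def clean(read: Read) -> Optional[Read]:
        clipped = clip_adapter(read, adapter, clip_min_overlap, clip_max_mismatch_frac)
        if len(clipped) < len(read):
            stats.clipped += 1
        trimmed = quality_trim(clipped, q_threshold, min_length)
        if trimmed is None:
            stats.discarded += 1
        return trimmed

    cleaned_pairs: list[tuple[Optional[Read], Optional[Read]]] = []
    for fwd, rev in pairs:
        cf, cr = clean(fwd), clean(rev)
        if (cf is None) != (cr is None):
            stats.orphans += 1
        cleaned_pairs.append((cf, cr))
    cleaned_singletons = [s for s in (clean(r) for r in singletons) if s is not None]

    merged_set, paired_set, combined_set = prepare_modes(
        cleaned_pairs, cleaned_singletons, merge_min_overlap, merge_max_mismatch_frac
    )
    stats.merged = sum(1 for r in merged_set.reads if r.mate is Mate.MERGED)
    return merged_set, paired_set, combined_set, stats
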