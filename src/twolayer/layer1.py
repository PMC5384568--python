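"""First assembly layer: per-k de Bruijn graphs over canonical k-mers.

Nodes are (k-1)-mers, edges are observed k-mers with their multiplicities;
both strands are represented through canonical form (the lexicographically
smaller of a k-mer and its reverse complement), and k is required to be odd
so no k-mer is its own reverse complement. Contigs are the spellings of
maximal unbranched paths (unitigs) of the cleaned graph — no scaffolding,
no gap characters. The layer runs once per k in a list spanning both the
short and long reads of the library; large k values that exceed every read
simply yield an empty assembly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

from .preprocess import Read, ReadSet
from .seq import canonical, revcomp

logger = logging.getLogger(__name__)

DEFAULT_K_LIST = (37, 47, 57, 67, 77, 87, 97, 107, 117, 127)

_ACGT = frozenset("ACGT")


@dataclass
class Contig:
    """An assembled sequence with provenance and (optional) read support."""

    id: str
    sequence: str
    provenance: tuple = (1, None, "")  # (layer, k or "merge", source id)
    support: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class KmerGraph:
    """Canonical-k-mer multiset view of a bidirected de Bruijn graph."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for kmer in self.counts:
            out.add(canonical(kmer[:-1]))
            out.add(canonical(kmer[1:]))
        return out


def _read_sequences(reads: Union[ReadSet, Iterable]) -> list[str]:
    if isinstance(reads, ReadSet):
        return reads.sequences()
    out = []
    for r in reads:
        out.append(r.sequence if isinstance(r, Read) else str(r))
    return out


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_graph(reads: Union[ReadSet, Iterable], k: int) -> KmerGraph:
    """Count every length-k substring of every read in canonical form.

    Reads shorter than k contribute nothing; k-mers containing a non-ACGT
    character are skipped. Even k is rejected (a k-mer could equal its own
    reverse complement, making strand canonicalization ambiguous).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k < 3:
        raise ValueError("k must be >= 3")
    counts: dict[str, int] = {}
    for seq in _read_sequences(reads):
        n = len(seq)
        if n < k:
            continue
        if set(seq) <= _ACGT:
            bad_before = [0] * (n + 1)  # all clean: fast path below
        else:
            bad_before = [0] * (n + 1)
            for i, base in enumerate(seq):
                bad_before[i + 1] = bad_before[i] + (base not in _ACGT)
        for i in range(n - k + 1):
            if bad_before[i + k] - bad_before[i]:
                continue
            kmer = canonical(seq[i:i + k])
            counts[kmer] = counts.get(kmer, 0) + 1
    return KmerGraph(k=k, counts=counts)


# ---------------------------------------------------------------------------
# Unitig machinery (shared by cleaning and contig extraction)
# ---------------------------------------------------------------------------

def _fwd_exts(counts: dict[str, int], kmer: str) -> list[str]:
    suffix = kmer[1:]
    return [b for b in "ACGT" if canonical(suffix + b) in counts]


def _bwd_exts(counts: dict[str, int], kmer: str) -> list[str]:
    prefix = kmer[:-1]
    return [b for b in "ACGT" if canonical(b + prefix) in counts]


def _unitigs(counts: dict[str, int]) -> list[tuple[str, list[str]]]:
    """Maximal unbranched k-mer paths as (spelling, canonical k-mer list).

    Each canonical k-mer is spelled exactly once. Deterministic: seeds are
    visited in sorted order and extensions probed in A<C<G<T order.
    """
    used: set[str] = set()
    unitigs: list[tuple[str, list[str]]] = []
    for seed in sorted(counts):
        if seed in used:
            continue
        used.add(seed)
        path = [seed]
        cur = seed
        while True:  # extend right
            exts = _fwd_exts(counts, cur)
            if len(exts) != 1:
                break
            nxt = cur[1:] + exts[0]
            if canonical(nxt) in used or len(_bwd_exts(counts, nxt)) != 1:
                break
            used.add(canonical(nxt))
            path.append(nxt)
            cur = nxt
        cur = seed
        left: list[str] = []
        while True:  # extend left
            exts = _bwd_exts(counts, cur)
            if len(exts) != 1:
                break
            prv = exts[0] + cur[:-1]
            if canonical(prv) in used or len(_fwd_exts(counts, prv)) != 1:
                break
            used.add(canonical(prv))
            left.append(prv)
            cur = prv
        path = left[::-1] + path
        spelling = path[0] + "".join(p[-1] for p in path[1:])
        unitigs.append((spelling, [canonical(p) for p in path]))
    return unitigs


# ---------------------------------------------------------------------------
# Graph cleaning
# ---------------------------------------------------------------------------

def clean_graph(
    graph: KmerGraph, min_coverage: int = 2, max_tip_length: int | None = None
) -> KmerGraph:
    """Remove low-coverage k-mers, short dead-end tips, and simple bubbles.

    Tips (unitigs dead at exactly one end) shorter than ``max_tip_length``
    (default 2k) are clipped iteratively to a fixpoint; two-path bubbles
    sharing both endpoint nodes collapse onto the higher-coverage path.
    """
    if min_coverage < 0 or (max_tip_length is not None and max_tip_length < 0):
        raise ValueError("cleaning parameters must be >= 0")
    k = graph.k
    if max_tip_length is None:
        max_tip_length = 2 * k
    counts = {
        kmer: c for kmer, c in graph.counts.items() if c >= min_coverage
    }

    def drop(kmers: Iterable[str]) -> None:
        for kmer in kmers:
            counts.pop(kmer, None)

    changed = True
    while changed:
        changed = False
        # --- tips -------------------------------------------------------
        while True:
            removed = False
            for spelling, kmers in _unitigs(counts):
                first, last = kmers[0], kmers[-1]
                # recover oriented ends from the spelling itself
                start_or = spelling[:k]
                end_or = spelling[-k:]
                dead_left = len(_bwd_exts(counts, start_or)) == 0
                dead_right = len(_fwd_exts(counts, end_or)) == 0
                if dead_left != dead_right and len(spelling) < max_tip_length:
                    drop(kmers)
                    removed = True
                    changed = True
            if not removed:
                break
        # --- simple bubbles ----------------------------------------------
        # Parallel unitigs between the same junction nodes are a bubble
        # only when both branches are short and of similar length (a point
        # divergence); long parallel paths between repeat boundaries are
        # genuine genome segments and must be kept.
        max_bubble = 3 * k
        groups: dict[tuple[str, str], list[tuple[str, list[str]]]] = {}
        for spelling, kmers in _unitigs(counts):
            u = spelling[: k - 1]
            v = spelling[-(k - 1):]
            key = min((u, v), (revcomp(v), revcomp(u)))
            groups.setdefault(key, []).append((spelling, kmers))
        for members in groups.values():
            if len(members) < 2:
                continue
            longest = max(len(s) for s, _ in members)
            if longest > max_bubble or any(
                len(s) < 0.9 * longest for s, _ in members
            ):
                continue
            def mean_cov(item: tuple[str, list[str]]) -> float:
                return sum(counts[km] for km in item[1]) / len(item[1])
            members.sort(key=lambda m: (-mean_cov(m), m[0]))
            for _, kmers in members[1:]:
                drop(kmers)
                changed = True
    return KmerGraph(k=k, counts=counts)


# ---------------------------------------------------------------------------
# Contig extraction and the multi-k sweep
# ---------------------------------------------------------------------------

def extract_contigs(graph: KmerGraph) -> list[Contig]:
    """Spell maximal unbranched paths of a (cleaned) graph into contigs.

    Output is deterministic: each contig is emitted in its lexicographically
    smaller orientation and the list is sorted by sequence.
    """
    spellings = []
    for spelling, _ in _unitigs(graph.counts):
        rc = revcomp(spelling)
        spellings.append(spelling if spelling <= rc else rc)
    spellings.sort()
    return [
        Contig(id=f"k{graph.k}_{i}", sequence=s, provenance=(1, graph.k, f"k{graph.k}"))
        for i, s in enumerate(spellings)
    ]


def multi_k_assemble(
    reads: Union[ReadSet, Iterable],
    k_list: Sequence[int] = DEFAULT_K_LIST,
    min_coverage: int = 2,
    max_tip_length: int | None = None,
) -> list[tuple[int, list[Contig]]]:
    """One independent de Bruijn assembly per k value.

    Contig ids are globally unique across the sweep (``L1|k{K}|{serial}``).
    A k exceeding every read length yields an empty assembly with a warning.
    """
    if not k_list:
        raise ValueError("k_list must be non-empty")
    if any(k % 2 == 0 for k in k_list):
        raise ValueError("all k values must be odd")
    sequences = _read_sequences(reads)
    assemblies: list[tuple[int, list[Contig]]] = []
    for k in k_list:
        graph = clean_graph(build_graph(sequences, k), min_coverage, max_tip_length)
        contigs = extract_contigs(graph)
        for i, contig in enumerate(contigs):
            contig.id = f"L1|k{k}|{i}"
        if not contigs:
            logger.warning("k=%d produced no contigs (k may exceed read lengths)", k)
        assemblies.append((k, contigs))
    return assemblies
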