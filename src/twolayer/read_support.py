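"""Read-incoherence filter: map reads back to contigs, drop unsupported ones.

De Bruijn assembly can chain k-mers coming from different reads that never
co-occurred in any molecule, producing "read-incoherent" contigs. The filter
re-maps the input reads against each assembly with a minimal seed-and-extend
aligner (exact k-mer seeds, ungapped extension, both strands) and removes
every contig that no read supports.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .layer1 import Contig
from .preprocess import Read, ReadSet
from .seq import revcomp, seq_to_array

DEFAULT_SEED_LENGTH = 15


@dataclass
class SupportRecord:
    contig_id: str
    count: int
    best_identity: float


def _sequences(reads: Union[ReadSet, Iterable]) -> list[str]:
    if isinstance(reads, ReadSet):
        return reads.sequences()
    return [r.sequence if isinstance(r, Read) else str(r) for r in reads]


def _seed_index(
    contigs: Sequence[Contig], seed_len: int
) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ci, contig in enumerate(contigs):
        seq = contig.sequence
        for pos in range(len(seq) - seed_len + 1):
            index.setdefault(seq[pos:pos + seed_len], []).append((ci, pos))
    return index


def align_reads_to_contigs(
    reads: Union[ReadSet, Iterable],
    contigs: Sequence[Contig],
    min_identity: float = 0.95,
    min_read_cover: float = 0.9,
    seed_len: int = DEFAULT_SEED_LENGTH,
) -> list[SupportRecord]:
    """Count, per contig, the reads aligning to it on either strand.

    A read supports a contig when some ungapped placement (anchored by an
    exact ``seed_len``-mer) covers at least ``min_read_cover`` of the read
    at identity >= ``min_identity``. Every contig receives a record.
    """
    if not contigs:
        raise ValueError("contigs must be non-empty")
    index = _seed_index(contigs, seed_len)
    carrs = [seq_to_array(c.sequence) for c in contigs]
    counts = [0] * len(contigs)
    best = [0.0] * len(contigs)
    for seq in _sequences(reads):
        n = len(seq)
        if n < seed_len:
            continue
        supported: set[int] = set()
        for oriented in (seq, revcomp(seq)):
            rarr = seq_to_array(oriented)
            offsets = list(range(0, n - seed_len + 1, seed_len))
            if offsets[-1] != n - seed_len:
                offsets.append(n - seed_len)
            tried: set[tuple[int, int]] = set()
            for off in offsets:
                for ci, pos in index.get(oriented[off:off + seed_len], ()):
                    start = pos - off  # read start on the contig
                    if (ci, start) in tried:
                        continue
                    tried.add((ci, start))
                    carr = carrs[ci]
                    r0 = max(0, -start)
                    r1 = min(n, len(carr) - start)
                    span = r1 - r0
                    if span < min_read_cover * n:
                        continue
                    matches = int(
                        np.count_nonzero(rarr[r0:r1] == carr[start + r0:start + r1])
                    )
                    identity = matches / span
                    if identity >= min_identity:
                        supported.add(ci)
                        if identity > best[ci]:
                            best[ci] = identity
        for ci in supported:
            counts[ci] += 1
    return [
        SupportRecord(contig.id, counts[ci], best[ci])
        for ci, contig in enumerate(contigs)
    ]


def filter_unsupported(
    contigs: Sequence[Contig], records: Sequence[SupportRecord]
) -> list[Contig]:
    """Keep exactly the contigs with at least one supporting read.

    Support counts are attached to the surviving contigs; a contig with no
    record is a hard error.
    """
    by_id = {rec.contig_id: rec for rec in records}
    kept = []
    for contig in contigs:
        rec = by_id.get(contig.id)
        if rec is None:
            raise ValueError(f"no support record for contig {contig.id}")
        if rec.count >= 1:
            contig.support = rec.count
            kept.append(contig)
    return kept
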