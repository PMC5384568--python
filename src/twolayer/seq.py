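"""Shared sequence primitives and plain-text I/O (FASTA/FASTQ/BED/TSV).

All coordinates in this package are 0-based half-open. Sequences are plain
Python strings over {A,C,G,T,N}; per-base qualities are lists of Phred ints.
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a sequence for vectorised base-wise comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with open_text(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open_text(path, "wt") as handle:
        SeqIO.write(recs, handle, "fasta")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)
# ---------------------------------------------------------------------------

def quals_to_string(quals: Iterable[int]) -> str:
    return "".join(chr(min(q, 93) + 33) for q in quals)


def string_to_quals(qstring: str) -> list[int]:
    return [ord(c) - 33 for c in qstring]


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, sequence, qualities) from a Phred+33 FASTQ file."""
    with open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq.upper(), string_to_quals(qual)


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, Iterable[int]]]) -> None:
    with open_text(path, "wt") as handle:
        for name, seq, quals in reads:
            handle.write(f"@{name}\n{seq}\n+\n{quals_to_string(quals)}\n")


# ---------------------------------------------------------------------------
# BED (0-based half-open) and small TSV helpers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    rows = []
    with open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            name = fields[3] if len(fields) > 3 else ""
            rows.append((fields[0], int(fields[1]), int(fields[2]), name))
    return rows


def write_bed(path: str | Path, rows: Iterable[tuple[str, int, int, str]]) -> None:
    with open_text(path, "wt") as handle:
        for chrom, start, end, name in rows:
            handle.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def n50(lengths: Iterable[int]) -> int:
    """Largest L such that contigs >= L sum to at least half the total length."""
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    if total == 0:
        return 0
    acc = 0
    for length in lengths:
        acc += length
        if 2 * acc >= total:
            return length
    return lengths[-1]
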