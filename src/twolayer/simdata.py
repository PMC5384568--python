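"""Synthetic ancient-DNA sequencing data with ground truth.

Degraded DNA libraries have a characteristic statistical signature: inserts
of only a few tens of base pairs (typically 44-172 bp), adapter read-through
whenever the insert is shorter than the read, largely overlapping mate
pairs, and C->T substitutions from cytosine deamination that concentrate at
fragment termini (G->A at the 3' end, the complementary-strand view).
This module simulates a bacterial-style circular genome with planted repeat
families and a paired-end library with exactly those properties, emitting
FASTQ/FASTA/BED plus a fragment-origin table so every downstream claim can
be checked against ground truth.

Everything is a pure function of ``SimConfig.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .preprocess import DEFAULT_ADAPTER, Mate, Read
from .seq import revcomp, write_bed, write_fasta, write_fastq

_BASES = "ACGT"


class SimConfigError(ValueError):
    """Invalid or unsatisfiable simulation configuration."""


@dataclass(frozen=True)
class FragmentLengthModel:
    """Insert-length distribution: truncated normal on [min, max], or an
    explicit empirical histogram ({length: weight})."""

    min: int = 44
    max: int = 172
    mean: float = 88.0
    sd: float = 25.0
    histogram: Optional[dict[int, float]] = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.histogram:
            lengths = np.array(sorted(self.histogram), dtype=int)
            weights = np.array([self.histogram[l] for l in lengths], dtype=float)
            return rng.choice(lengths, size=n, p=weights / weights.sum())
        a = (self.min - self.mean) / self.sd
        b = (self.max - self.mean) / self.sd
        draws = truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)
        return np.clip(np.rint(draws).astype(int), self.min, self.max)

    @property
    def mean_length(self) -> float:
        if self.histogram:
            total = sum(self.histogram.values())
            return sum(l * w for l, w in self.histogram.items()) / total
        return self.mean


@dataclass(frozen=True)
class QualityModel:
    """Two-level base qualities: ``high_q`` everywhere, ``low_q`` at
    sequencing-error positions when ``couple_errors`` is set, ``pad_q`` on
    padding bases past the adapter."""

    high_q: int = 37
    low_q: int = 15
    couple_errors: bool = True
    pad_q: int = 2


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 50_000
    # (unit_length, copy_number, divergence) per repeat family
    repeat_specs: tuple[tuple[int, int, float], ...] = ((100, 3, 0.0),)
    gc_content: float = 0.5
    fragment_length_model: FragmentLengthModel = field(default_factory=FragmentLengthModel)
    target_coverage: float = 30.0
    read_length: int = 101
    adapter_sequence: str = DEFAULT_ADAPTER
    sequencing_error_rate: float = 0.0
    damage_rate_5p: float = 0.0
    damage_decay: float = 0.5
    quality_model: QualityModel = field(default_factory=QualityModel)
    circular: bool = True
    seed: int = 0

    def validate(self) -> None:
        flm = self.fragment_length_model
        if self.genome_length <= 0 or self.read_length <= 0:
            raise SimConfigError("genome_length and read_length must be positive")
        for name, p in [
            ("gc_content", self.gc_content),
            ("sequencing_error_rate", self.sequencing_error_rate),
            ("damage_rate_5p", self.damage_rate_5p),
            ("damage_decay", self.damage_decay),
        ]:
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        if flm.histogram is None and not flm.min <= flm.mean <= flm.max:
            raise SimConfigError("mean fragment length outside [min, max]")
        if flm.min > flm.max or flm.min < 1:
            raise SimConfigError("invalid fragment length bounds")
        for unit, copies, div in self.repeat_specs:
            if unit * copies >= self.genome_length:
                raise SimConfigError("repeat family does not fit in the genome")
            if not 0.0 <= div <= 1.0:
                raise SimConfigError("repeat divergence must lie in [0, 1]")
        if self.target_coverage < 0:
            raise SimConfigError("target_coverage must be >= 0")


@dataclass(frozen=True)
class RepeatAnnotation:
    """Sorted, in-bounds repeat intervals (start, end, family id)."""

    intervals: tuple[tuple[int, int, str], ...] = ()

    def total_bases(self) -> int:
        return sum(end - start for start, end, _ in self.intervals)


@dataclass(frozen=True)
class Genome:
    id: str
    sequence: str
    repeats: RepeatAnnotation = field(default_factory=RepeatAnnotation)
    circular: bool = True

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Fragment:
    """A sequenced (possibly damaged) DNA fragment.

    ``origin`` is (genome id, start, end, strand); on a circular genome
    ``end`` may exceed the genome length, meaning the fragment wraps past
    the origin of replication. Strand '-' means the fragment sequence is the
    reverse complement of the genome interval; the sequence is always 5'->3'.
    """

    origin: tuple[str, int, int, str]
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=probs)
    return "".join(_BASES[i] for i in idx)


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = rng.choice([b for b in _BASES if b != out[i]])
    return "".join(out)


def simulate_genome(config: SimConfig) -> Genome:
    """A random genome of exactly ``genome_length`` with every repeat spec
    planted as near-identical copies at non-overlapping loci."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    length = config.genome_length
    seq = list(_random_seq(rng, length, config.gc_content))
    placed: list[tuple[int, int, str]] = []
    for fam_idx, (unit, copies, divergence) in enumerate(config.repeat_specs):
        family = f"rep{fam_idx}"
        master = _random_seq(rng, unit, config.gc_content)
        for _ in range(copies):
            for _attempt in range(1000):
                start = int(rng.integers(0, length - unit + 1))
                end = start + unit
                if all(end <= s or start >= e for s, e, _ in placed):
                    break
            else:
                raise SimConfigError(
                    f"cannot place {copies} copies of a {unit} bp repeat "
                    f"in a {length} bp genome"
                )
            copy_seq = _diverge(rng, master, divergence)
            seq[start:end] = copy_seq
            placed.append((start, end, family))
    placed.sort()
    return Genome(
        id=f"sim|len={length}|seed={config.seed}",
        sequence="".join(seq),
        repeats=RepeatAnnotation(tuple(placed)),
        circular=config.circular,
    )


# ---------------------------------------------------------------------------
# Fragment simulation
# ---------------------------------------------------------------------------

def simulate_fragments(genome: Genome, config: SimConfig) -> list[Fragment]:
    """Uniformly placed fragments at ~``target_coverage`` fold coverage.

    Fragment count is round(coverage * genome_length / mean fragment
    length); positions and strands are uniform. On circular genomes
    fragments may wrap the origin; on linear genomes start positions are
    restricted so fragments fit.
    """
    config.validate()
    flm = config.fragment_length_model
    rng = np.random.default_rng([config.seed, 1])
    length = len(genome)
    n = int(round(config.target_coverage * length / flm.mean_length))
    if n == 0:
        return []
    lengths = flm.sample(n, rng)
    if genome.circular:
        starts = rng.integers(0, length, size=n)
    else:
        starts = np.array(
            [rng.integers(0, max(length - l, 0) + 1) for l in lengths], dtype=int
        )
    strands = rng.integers(0, 2, size=n)
    doubled = genome.sequence + genome.sequence[: int(lengths.max())]
    fragments = []
    for start, flen, strand_bit in zip(starts.tolist(), lengths.tolist(), strands.tolist()):
        sub = doubled[start:start + flen]
        strand = "+" if strand_bit == 0 else "-"
        if strand == "-":
            sub = revcomp(sub)
        fragments.append(Fragment((genome.id, start, start + flen, strand), sub))
    return fragments


# ---------------------------------------------------------------------------
# Deamination damage
# ---------------------------------------------------------------------------

def apply_damage(
    fragment: Fragment, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Fragment:
    """C->T at 5'-offset i with probability rate * decay^i, and G->A
    symmetrically from the 3' end. Positions are independent."""
    rate, decay = config.damage_rate_5p, config.damage_decay
    if rate <= 0:
        return fragment
    if rng is None:
        _, start, end, strand = fragment.origin
        rng = np.random.default_rng(
            [config.seed, 2, start, end, 0 if strand == "+" else 1]
        )
    seq = list(fragment.sequence)
    n = len(seq)
    u5 = rng.random(n)
    u3 = rng.random(n)
    for i in range(n):
        if seq[i] == "C" and u5[i] < rate * decay**i:
            seq[i] = "T"
        j = n - 1 - i  # offset from the 3' end
        if seq[j] == "G" and u3[i] < rate * decay**i:
            seq[j] = "A"
    return replace(fragment, sequence="".join(seq))


# ---------------------------------------------------------------------------
# Paired-end sequencing
# ---------------------------------------------------------------------------

def sequence_paired_end(
    fragment: Fragment,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    name: Optional[str] = None,
) -> tuple[Read, Read]:
    """Sequence a fragment from both ends.

    Each read carries ``read_length`` bases: the fragment (from the
    respective end, reverse-complemented for the reverse read), continuing
    into the adapter and finally 'A' padding at ``pad_q`` when the fragment
    plus adapter is still shorter than the read. Substitution errors are
    applied at ``sequencing_error_rate`` to sequenced (non-padding) bases.
    """
    if config.read_length <= 0 or not config.adapter_sequence:
        raise SimConfigError("read_length must be > 0 and adapter non-empty")
    if rng is None:
        _, start, end, strand = fragment.origin
        rng = np.random.default_rng(
            [config.seed, 3, start, end, 0 if strand == "+" else 1]
        )
    if name is None:
        _, start, end, strand = fragment.origin
        name = f"sim:{start}-{end}:{strand}"
    qm = config.quality_model

    def one_read(template: str, mate: Mate, suffix: str) -> Read:
        core = (template + config.adapter_sequence)[: config.read_length]
        pad = config.read_length - len(core)
        seq = list(core)
        quals = [qm.high_q] * len(core)
        if config.sequencing_error_rate > 0:
            hits = np.flatnonzero(rng.random(len(core)) < config.sequencing_error_rate)
            for i in hits:
                seq[i] = rng.choice([b for b in _BASES if b != seq[i]])
                if qm.couple_errors:
                    quals[i] = qm.low_q
        seq.extend("A" * pad)
        quals.extend([qm.pad_q] * pad)
        return Read(f"{name}{suffix}", "".join(seq), quals, mate)

    forward = one_read(fragment.sequence, Mate.FORWARD, "/1")
    reverse = one_read(revcomp(fragment.sequence), Mate.REVERSE, "/2")
    return forward, reverse


# ---------------------------------------------------------------------------
# Whole-library convenience and on-disk interface
# ---------------------------------------------------------------------------

def simulate_library(
    config: SimConfig,
) -> tuple[Genome, list[Fragment], list[tuple[Read, Read]]]:
    """Genome -> fragments -> damage -> paired reads, one shared RNG stream
    per stage so the whole library is a pure function of the seed."""
    genome = simulate_genome(config)
    fragments = simulate_fragments(genome, config)
    damage_rng = np.random.default_rng([config.seed, 2])
    seq_rng = np.random.default_rng([config.seed, 3])
    pairs = []
    damaged = []
    for idx, frag in enumerate(fragments):
        frag = apply_damage(frag, config, rng=damage_rng)
        damaged.append(frag)
        pairs.append(
            sequence_paired_end(frag, config, rng=seq_rng, name=f"sim:{idx}")
        )
    return genome, damaged, pairs


def write_library(
    outdir: str | Path,
    genome: Genome,
    fragments: Sequence[Fragment],
    pairs: Sequence[tuple[Read, Read]],
    prefix: str = "sim",
) -> dict[str, Path]:
    """Write genome FASTA, repeat BED, paired FASTQ and fragment-origin TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / f"{prefix}_genome.fasta",
        "repeats": outdir / f"{prefix}_repeats.bed",
        "r1": outdir / f"{prefix}_R1.fastq",
        "r2": outdir / f"{prefix}_R2.fastq",
        "truth": outdir / f"{prefix}_fragments.tsv",
    }
    write_fasta(paths["genome"], [(genome.id, genome.sequence)])
    write_bed(
        paths["repeats"],
        [(genome.id, s, e, fam) for s, e, fam in genome.repeats.intervals],
    )
    write_fastq(paths["r1"], [(f.id, f.sequence, f.qualities) for f, _ in pairs])
    write_fastq(paths["r2"], [(r.id, r.sequence, r.qualities) for _, r in pairs])
    with open(paths["truth"], "w") as handle:
        handle.write("read_id\tgenome_id\tstart\tend\tstrand\n")
        for frag, (fwd, _) in zip(fragments, pairs):
            gid, start, end, strand = frag.origin
            base = fwd.id[:-2]
            handle.write(f"{base}\t{gid}\t{start}\t{end}\t{strand}\n")
    return paths
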