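# Methods

## The assembly model

`twolayer` assembles short-fragment DNA in two stages. The first stage is a
textbook de Bruijn assembler run once per k: every length-k substring of
every read is counted in canonical form (the lexicographically smaller of
the k-mer and its reverse complement; k must be odd so no k-mer is its own
reverse complement), and contigs are the spellings of maximal unbranched
paths of the resulting bidirected graph. No scaffolding or gap filling is
attempted and mate-pair distance information is deliberately ignored: with
inserts this short almost every pair overlaps and is merged during
preprocessing, so pairing carries essentially no extra long-range signal.
Reads from the PAIRED treatment are therefore assembled as single reads.

The second stage treats the pooled per-k contigs as the reads of an
overlap-layout assembly with *exact* suffix–prefix overlaps. Exactness is
deliberate: first-layer consensus has already averaged out sequencing
errors, so on a single-genome sample true contig overlaps are exact and any
mismatch indicates divergent origin. The stage performs, in order:

1. duplicate/containment removal (a contig equal to, or a substring of,
   another contig on either strand is dropped; among exact duplicates the
   lexicographically smallest id survives);
2. greedy unambiguous merging: A+B are merged when B is the only overlap
   partner at A's 3' end and A the only partner at B's 5' end. Every such
   merge is forced, so the fixpoint is independent of processing order
   (verified by permutation tests);
3. overlap-graph construction over oriented contigs (longest exact overlap
   ≥ `min_overlap` per oriented pair, found with a prefix-seed index whose
   output is contract-identical to the quadratic all-pairs scan);
4. transitive reduction: an edge a→c is removed from consideration when
   some b satisfies a→b→c with ov_bc = len(b) − ov_ab + ov_ac;
5. spelling of maximal unbranched paths (branches terminate paths — no
   repeat-resolution heuristics are layered on top) and a final length
   filter.

## Parameters

| parameter | default | role |
|---|---|---|
| k list | 37, 47, …, 127 (odd) | spans the merged-read length spectrum |
| graph `min_coverage` | 2 | k-mer multiplicity below which edges are noise |
| `max_tip_length` | 2k | dead-end paths shorter than this are clipped |
| bubble cap | 3k, ≤10% length difference | only point-divergence bubbles collapse |
| clip `min_overlap` / mismatch | 3 / 0.10 | terminal adapter match admissibility |
| quality trim | Q20, min length 25 | 3'-only trimming, short survivors dropped |
| merge `min_overlap` / mismatch | 10 / 0.05 | admissible pair-overlap placements |
| support `min_identity` / `min_read_cover` / seed | 0.95 / 0.9 / 15 | what "supported by a read" means |
| layer-2 `min_overlap` | 45 bp | far above chance matches at contig scale |
| `min_final_length` | 1,000 bp | final contig length filter |
| mapping seed / identity | 31-mer / 0.9 | contig-to-reference alignment |

All of these surface in `PipelineConfig` (one YAML document drives the
pipeline) and in the per-module function signatures.

## The simulator

The generator emulates the statistical structure of degraded-DNA libraries
from circular bacterial chromosomes:

* **Genome.** Uniform random sequence at a configurable GC content with
  repeat families planted as near-identical copies at non-overlapping
  loci, every copy annotated. Genomes are circular by default — the
  natural topology for bacterial replicons, and the only one under which
  uniformly placed fragments cover every base, so a clean library can
  assemble into a single contig spelling the whole genome. That contig
  carries k−1 wrap bases; identity to the genome is judged up to rotation
  and reverse complement.
* **Fragments.** Truncated-normal insert lengths on [44, 172] with mean
  88 bp and sd 25 bp by default (an explicit empirical histogram can be
  supplied instead); uniform positions and strands. Fragment count is
  coverage × genome length / mean insert length.
* **Damage.** C→T at 5'-offset i with probability rate × decay^i and G→A
  symmetrically from the 3' end — the standard exponentially decaying
  terminal deamination profile. Defaults are rate 0.1, decay 0.5; a
  UDG-treated library corresponds to rate 0 (`--udg` on the CLI). The
  published samples this design targets were UDG-treated, so the
  error-free studies set the rate to 0.
* **Reads.** Each read carries `read_length` bases: fragment, then adapter
  read-through, then 'A' padding at Q2 when fragment+adapter is still too
  short. Substitution errors at a configurable rate; qualities are
  two-level (Q37, with Q15 at error positions when the coupling flag is
  set). No indel errors, no PCR duplicates, no metagenomic background —
  passing tests therefore demonstrate the method's behaviour on a clean
  single-genome signal, not robustness to contamination or indel noise.

The whole library is a pure function of the seed (per-stage RNG streams),
so every FASTQ byte reproduces.

## Numerical and determinism choices

* Contigs are always emitted in their lexicographically smaller
  orientation and sorted; graph walks visit seeds in sorted order with
  extensions probed in A<C<G<T order. Two runs of the pipeline from the
  same configuration are byte-identical.
* Pair merging slides the reverse-complemented mate over *all* relative
  shifts, including negative ones (the read-through geometry of inserts
  shorter than the read). Overhangs beyond the biological fragment — the
  reverse read's bases left of the forward read's start, the forward
  read's bases right of the reverse read's 5' terminus — are adapter
  remnants and are trimmed. The placement with the most matching bases
  wins; ties go to the longer overlap. At a disagreeing overlap position
  the higher-quality base wins with quality max(|q1−q2|, 2); on a quality
  tie the forward base is kept at Q2.
* Bubble collapsing is restricted to parallel unitigs that are short
  (≤ 3k) and of near-equal length; long parallel paths sharing junction
  nodes are genuine inter-repeat segments, not bubbles.
* The read-support aligner is intentionally minimal: exact 15-mer seeds,
  ungapped extension, both strands. The filter needs presence/absence of a
  coherent read placement, not optimal alignment, and the simulator
  produces substitution-only noise.
* Degenerate inputs: empty assemblies at large k are legal (warning);
  an all-k-empty layer 1 aborts with a stage-labelled diagnostic; an empty
  contig set reports zeroed statistics; repeat resolution without
  annotated repeat bases reports not-applicable.

## Study sizes

The bundled studies use a 50 kb standard genome (three identical 100 bp
repeat copies, 30× error-free coverage, merged reads, all ten k values), a
20 kb repeat-free genome for the perfect-recovery study, ~1,100 pairs for
the merge study and ~50,000 fragments for the damage calibration. These
sizes are large enough that every contrast of interest (single-k breakage
vs two-layer bridging, repeat gaps vs coverage holes) is expressed, while a
full pipeline run completes in well under a minute on one core.

## Known limitations

* Near-duplicate (non-exact) redundancy among pooled contigs can persist
  into the final assembly: layer 2 removes exact duplicates and
  containments only, so the duplicated-coverage fraction typically rises
  slightly after the second layer. This is tracked (`duplicated_fraction`)
  but not suppressed.
* Layer 2 stops at branches; repeats longer than the largest productive
  k−1 remain unresolved by design.
* Gap counts depend on the contig-to-reference aligner's split-alignment
  behaviour; only relative (layer-1 vs layer-2) comparisons are asserted.
* The aligners are exact-seed based: a contig whose every 31-mer is
  mutated relative to the reference (identity < ~0.97 uniformly) would be
  missed; at the simulator's noise levels this does not occur.
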