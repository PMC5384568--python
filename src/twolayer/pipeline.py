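"""End-to-end orchestration of the two-layer assembly workflow.

simulate (or load) reads -> preprocess -> per-k de Bruijn assemblies ->
read-support filter -> pooled string-overlap meta-assembly -> evaluation.
Every intermediate artifact is written to the output directory and a
manifest records parameters, seed and per-stage counts, so a rerun with the
same configuration reproduces identical outputs byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .evaluate import DEFAULT_THRESHOLDS, AssemblyReport, evaluate_assembly
from .layer1 import DEFAULT_K_LIST, Contig, multi_k_assemble
from .layer2 import (
    DEFAULT_MIN_FINAL_LENGTH,
    DEFAULT_MIN_OVERLAP,
    pool_contigs,
    remove_duplicates,
    fm_merge,
    build_overlap_graph,
    assemble_paths,
)
from .preprocess import DEFAULT_ADAPTER, Mode, Read, ReadSet, preprocess_pairs
from .read_support import align_reads_to_contigs, filter_unsupported
from .seq import read_bed, read_fasta, read_fastq, write_fasta
from .simdata import (
    FragmentLengthModel,
    Genome,
    QualityModel,
    RepeatAnnotation,
    SimConfig,
    simulate_library,
    write_library,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # input: either a simulation or FASTQ paths (+ reference for evaluation)
    sim: Optional[SimConfig] = field(default_factory=SimConfig)
    r1: Optional[str] = None
    r2: Optional[str] = None
    reference_fasta: Optional[str] = None
    repeats_bed: Optional[str] = None
    # preprocessing
    mode: Mode = Mode.MERGED
    adapter: str = DEFAULT_ADAPTER
    # layer 1
    k_list: tuple[int, ...] = DEFAULT_K_LIST
    min_coverage: int = 2
    max_tip_length: Optional[int] = None
    # read support
    support_min_identity: float = 0.95
    support_min_read_cover: float = 0.9
    support_seed_len: int = 15
    # layer 2
    min_overlap: int = DEFAULT_MIN_OVERLAP
    min_final_length: int = DEFAULT_MIN_FINAL_LENGTH
    # evaluation
    eval_min_length: int = 1000
    eval_min_identity: float = 0.9
    eval_thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    # bookkeeping
    outdir: str = "twolayer_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if any(k % 2 == 0 for k in self.k_list) or not self.k_list:
            raise StageError("config", "k_list must be non-empty and all odd")
        if self.min_overlap <= 0 or self.min_final_length < 0:
            raise StageError("config", "thresholds must be positive")
        if self.sim is None and (self.r1 is None or self.r2 is None):
            raise StageError("config", "either a simulation or FASTQ inputs required")
        for path in (self.r1, self.r2, self.reference_fasta, self.repeats_bed):
            if path is not None and not Path(path).exists():
                raise StageError("config", f"input file not found: {path}")
        if self.sim is not None:
            self.sim.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        sim_raw = kwargs.pop("sim", None)
        if sim_raw is not None:
            flm = sim_raw.pop("fragment_length_model", None)
            qm = sim_raw.pop("quality_model", None)
            specs = sim_raw.pop("repeat_specs", None)
            sim_kwargs = dict(sim_raw)
            if flm is not None:
                sim_kwargs["fragment_length_model"] = FragmentLengthModel(**flm)
            if qm is not None:
                sim_kwargs["quality_model"] = QualityModel(**qm)
            if specs is not None:
                sim_kwargs["repeat_specs"] = tuple(tuple(s) for s in specs)
            kwargs["sim"] = SimConfig(**sim_kwargs)
        elif "r1" in kwargs:
            kwargs.setdefault("sim", None)
        if "mode" in kwargs:
            kwargs["mode"] = Mode(kwargs["mode"])
        if "k_list" in kwargs:
            kwargs["k_list"] = tuple(kwargs["k_list"])
        if "eval_thresholds" in kwargs:
            kwargs["eval_thresholds"] = tuple(kwargs["eval_thresholds"])
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, Mode):
                return obj.value
            if isinstance(obj, (list, tuple)):
                return [convert(x) for x in obj]
            return obj

        return convert(self)


@dataclass
class PipelineResult:
    final_contigs: list[Contig]
    reports: dict[str, AssemblyReport]
    manifest: dict
    outdir: Path


def _load_reads(config: PipelineConfig) -> list[tuple[Read, Read]]:
    r1 = [Read(rid, seq, quals) for rid, seq, quals in read_fastq(config.r1)]
    r2 = [Read(rid, seq, quals) for rid, seq, quals in read_fastq(config.r2)]
    if len(r1) != len(r2):
        raise StageError("input", "R1/R2 read counts differ")
    return list(zip(r1, r2))


def _load_reference(config: PipelineConfig) -> Optional[Genome]:
    if config.reference_fasta is None:
        return None
    records = read_fasta(config.reference_fasta)
    if not records:
        raise StageError("input", "reference FASTA is empty")
    rid, seq = records[0]
    repeats = RepeatAnnotation()
    if config.repeats_bed:
        rows = read_bed(config.repeats_bed)
        repeats = RepeatAnnotation(
            tuple(sorted((s, e, name) for _c, s, e, name in rows))
        )
    return Genome(id=rid, sequence=seq, repeats=repeats)


def run_two_layer(config: PipelineConfig) -> PipelineResult:
    """Run the full workflow and write all artifacts under config.outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int | dict] = {}

    # ------------------------------------------------------------- input
    if config.sim is not None:
        genome, fragments, pairs = simulate_library(config.sim)
        write_library(outdir, genome, fragments, pairs)
        reference: Optional[Genome] = genome
    else:
        pairs = _load_reads(config)
        reference = _load_reference(config)
    counts["pairs_in"] = len(pairs)

    # -------------------------------------------------------- preprocess
    try:
        merged_set, paired_set, combined_set, stats = preprocess_pairs(
            pairs, adapter=config.adapter
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise StageError("preprocess", str(exc)) from exc
    mode_sets = {
        Mode.MERGED: merged_set,
        Mode.PAIRED: paired_set,
        Mode.COMBINED: combined_set,
    }
    reads = mode_sets[config.mode]
    counts["preprocess"] = dataclasses.asdict(stats)
    counts["reads_for_assembly"] = len(reads)
    pd.DataFrame([dataclasses.asdict(stats)]).to_csv(
        outdir / "preprocess_log.tsv", sep="\t", index=False
    )

    # ----------------------------------------------------------- layer 1
    try:
        assemblies = multi_k_assemble(
            reads, config.k_list, config.min_coverage, config.max_tip_length
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("layer1", str(exc)) from exc
    if all(not contigs for _k, contigs in assemblies):
        raise StageError(
            "layer1",
            "no contigs at any k (are all k values larger than the reads?)",
        )
    summary_rows = []
    for k, contigs in assemblies:
        write_fasta(
            outdir / f"layer1_k{k}.fasta", [(c.id, c.sequence) for c in contigs]
        )
        lengths = [len(c.sequence) for c in contigs]
        from .seq import n50 as n50_of

        summary_rows.append(
            {
                "k": k,
                "n_contigs": len(contigs),
                "total_bp": sum(lengths),
                "n50": n50_of(lengths),
            }
        )
    pd.DataFrame(summary_rows).to_csv(
        outdir / "layer1_summary.tsv", sep="\t", index=False
    )
    counts["layer1_contigs"] = {str(k): len(c) for k, c in assemblies}

    # ------------------------------------------------------ read support
    filtered_assemblies: list[tuple[int, list[Contig]]] = []
    support_rows = []
    for k, contigs in assemblies:
        if not contigs:
            filtered_assemblies.append((k, []))
            continue
        try:
            records = align_reads_to_contigs(
                reads,
                contigs,
                config.support_min_identity,
                config.support_min_read_cover,
                config.support_seed_len,
            )
            kept = filter_unsupported(contigs, records)
        except Exception as exc:  # noqa: BLE001
            raise StageError("read_support", str(exc)) from exc
        filtered_assemblies.append((k, kept))
        for rec in records:
            support_rows.append(
                {
                    "contig_id": rec.contig_id,
                    "reads": rec.count,
                    "best_identity": round(rec.best_identity, 4),
                }
            )
        write_fasta(
            outdir / f"supported_k{k}.fasta", [(c.id, c.sequence) for c in kept]
        )
    pd.DataFrame(support_rows).to_csv(
        outdir / "read_support.tsv", sep="\t", index=False
    )
    counts["supported_contigs"] = {
        str(k): len(c) for k, c in filtered_assemblies
    }

    # ----------------------------------------------------------- layer 2
    try:
        pooled = pool_contigs(filtered_assemblies)
        unique = remove_duplicates(pooled)
        merged = fm_merge(unique, config.min_overlap)
        graph = build_overlap_graph(merged, config.min_overlap)
        final_contigs = assemble_paths(graph, config.min_final_length)
    except Exception as exc:  # noqa: BLE001
        raise StageError("layer2", str(exc)) from exc
    counts["layer2"] = {
        "pooled": len(pooled),
        "after_dedup": len(unique),
        "after_fm_merge": len(merged),
        "final": len(final_contigs),
    }
    write_fasta(outdir / "pooled.fasta", [(c.id, c.sequence) for c in unique])
    write_fasta(outdir / "layer2.fasta", [(c.id, c.sequence) for c in final_contigs])
    with open(outdir / "overlap_graph.tsv", "w") as handle:
        handle.write("a_id\ta_orient\tb_id\tb_orient\toverlap\treducible\n")
        for edge in graph.edges:
            handle.write(
                f"{edge.a[0]}\t{'+-'[edge.a[1]]}\t{edge.b[0]}\t{'+-'[edge.b[1]]}"
                f"\t{edge.length}\t{int(edge.reducible)}\n"
            )

    # -------------------------------------------------------- evaluation
    reports: dict[str, AssemblyReport] = {}
    if reference is not None:
        for k, contigs in filtered_assemblies:
            reports[f"layer1_k{k}"] = evaluate_assembly(
                f"layer1_k{k}",
                contigs,
                reference,
                config.eval_min_length,
                config.eval_min_identity,
                config.eval_thresholds,
            )
        reports["layer2"] = evaluate_assembly(
            "layer2",
            final_contigs,
            reference,
            config.eval_min_length,
            config.eval_min_identity,
            config.eval_thresholds,
        )
        with open(outdir / "reports.json", "w") as handle:
            json.dump(
                {name: rep.to_dict() for name, rep in reports.items()},
                handle,
                indent=2,
                sort_keys=True,
            )
        compare_assemblies(list(reports.values())).to_csv(
            outdir / "comparison.tsv", sep="\t"
        )

    manifest = {
        "version": __version__,
        "config": config.to_jsonable(),
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return PipelineResult(final_contigs, reports, manifest, outdir)


def compare_assemblies(reports: Sequence[AssemblyReport]) -> pd.DataFrame:
    """Side-by-side metric table with the per-column best value flagged.

    "Best" is the largest value for N50/mean/longest/coverage and the
    smallest for contig count, gaps and unresolved repeat fraction; ties
    are all flagged.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    df = pd.DataFrame(
        {
            "name": r.name,
            "n_contigs": r.n_contigs,
            "n50": r.n50,
            "mean_contig_length": round(r.mean_contig_length, 1),
            "longest_contig": r.longest_contig,
            "n_gaps": r.n_gaps,
            "covered_fraction": round(r.genome_covered_fraction, 6),
            "repeat_unresolved": (
                float("nan")
                if r.repeat_unresolved_fraction is None
                else round(r.repeat_unresolved_fraction, 6)
            ),
        }
        for r in reports
    ).set_index("name")
    directions = {
        "n_contigs": "min",
        "n50": "max",
        "mean_contig_length": "max",
        "longest_contig": "max",
        "n_gaps": "min",
        "covered_fraction": "max",
        "repeat_unresolved": "min",
    }
    for col, direction in directions.items():
        series = df[col]
        best = series.min() if direction == "min" else series.max()
        df[f"{col}_best"] = series == best
    return df
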