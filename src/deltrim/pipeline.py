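"""End-to-end driver: simulate -> map -> call -> trim -> evaluate.

One :class:`RunConfig` (a simulation config plus caller and trimmer
settings) fully determines a run: every stochastic stage draws from a
named substream of the single top-level seed, so stages can be re-run in
isolation and two runs with the same config produce byte-identical
outputs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .caller import (
    DISCORDANT_DELETION,
    InsertStats,
    call_deletions,
    classify_pairs,
    estimate_insert_stats,
)
from .core import DeletionCall, SVRecord
from .coverage import CoverageTrack, build_coverage, filter_unique_pairs
from .evaluate import (
    EvalRecord,
    EvalSummary,
    PairedComparison,
    compare_before_after,
    match_calls,
    summarize,
)
from .simulate import (
    SimConfig,
    add_substitutions,
    apply_svs,
    draw_sv_set,
    generate_pairs,
    project_to_reference,
    simulate_reference,
)
from .trim import TrimParams, TrimResult, trim_calls

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "sweep_trim_params"]

logger = logging.getLogger("deltrim")

# fixed substream labels so each stage has its own reproducible stream
_STAGES = ("reference", "svs", "apply", "substitutions", "pairs")


@dataclass(frozen=True)
class RunConfig:
    """Settings for one simulated calling-and-trimming experiment."""

    sim: SimConfig = field(default_factory=SimConfig)
    trim: TrimParams = field(default_factory=TrimParams)
    sd_multiplier: float = 3.0
    min_support: int = 2
    concordant_only: bool = False

    def stage_rngs(self) -> dict[str, np.random.Generator]:
        seqs = np.random.SeedSequence(self.sim.seed).spawn(len(_STAGES))
        return {name: np.random.default_rng(s) for name, s in zip(_STAGES, seqs)}


@dataclass
class PipelineResult:
    """Everything one run produced, kept in memory for inspection."""

    config: RunConfig
    svs: list[SVRecord]
    truth: list[SVRecord]  # DEL records only
    alignments: pd.DataFrame  # MAPQ-filtered pair table in reference coords
    insert_stats: InsertStats
    calls: list[DeletionCall]
    coverage: CoverageTrack
    trim_results: list[TrimResult]
    trimmed_calls: list[DeletionCall]
    raw_records: list[EvalRecord]
    trimmed_records: list[EvalRecord]
    raw_summary: EvalSummary
    trimmed_summary: EvalSummary
    comparison_upstream: PairedComparison
    comparison_downstream: PairedComparison


def run_pipeline(
    config: RunConfig,
    outdir: Optional[Path] = None,
    write_genomes: bool = False,
) -> PipelineResult:
    """Run the full experiment described by ``config``.

    When ``outdir`` is given, the truth BED, call BEDs, pair table,
    coverage bedGraph, audit log and summary TSV are written there
    (genome FASTAs only with ``write_genomes=True``, as they dominate the
    output size).
    """
    from . import __version__

    sim = config.sim
    logger.info(
        "deltrim %s seed=%d config_hash=%08x",
        __version__,
        sim.seed,
        zlib.crc32(repr(config).encode()),
    )
    rngs = config.stage_rngs()

    reference = simulate_reference(sim.genome_length, rngs["reference"])
    svs = draw_sv_set(sim, seed=rngs["svs"])
    truth = [sv for sv in svs if sv.sv_type == "DEL"]
    sample, cmap = apply_svs(reference, svs, rngs["apply"])
    sample = add_substitutions(sample, sim.substitution_rate, rngs["substitutions"])
    logger.info("simulated %d bp sample with %d deletions", len(sample), len(truth))

    sample_pairs = generate_pairs(sample, sim, rngs["pairs"])
    aligned = project_to_reference(sample_pairs, cmap, chrom=sim.chrom)
    aligned = filter_unique_pairs(aligned)
    logger.info(
        "generated %d pairs, %d uniquely mapped", len(sample_pairs), len(aligned)
    )

    stats = estimate_insert_stats(aligned, m=config.sd_multiplier)
    labels = classify_pairs(aligned, stats)
    discordant = aligned.loc[labels == DISCORDANT_DELETION]
    calls = call_deletions(discordant, min_support=config.min_support)
    logger.info(
        "insert mu=%.1f sigma=%.1f; %d discordant pairs -> %d calls",
        stats.mu,
        stats.sigma,
        len(discordant),
        len(calls),
    )

    track = build_coverage(
        aligned,
        sim.chrom,
        0,
        sim.genome_length,
        concordant_only=config.concordant_only,
    )
    results = trim_calls(calls, track, config.trim)
    trimmed = [r.trimmed for r in results if r.trimmed is not None]
    logger.info(
        "trimmed %d/%d calls (%d removed)",
        sum(1 for r in results if r.trim_up or r.trim_down),
        len(results),
        sum(1 for r in results if r.removed),
    )

    raw_records = match_calls(calls, truth)
    trimmed_records = match_calls(trimmed, truth)
    result = PipelineResult(
        config=config,
        svs=svs,
        truth=truth,
        alignments=aligned,
        insert_stats=stats,
        calls=calls,
        coverage=track,
        trim_results=results,
        trimmed_calls=trimmed,
        raw_records=raw_records,
        trimmed_records=trimmed_records,
        raw_summary=summarize(raw_records, truth),
        trimmed_summary=summarize(trimmed_records, truth),
        comparison_upstream=compare_before_after(raw_records, trimmed_records, "upstream"),
        comparison_downstream=compare_before_after(
            raw_records, trimmed_records, "downstream"
        ),
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir), reference, sample, write_genomes)
    return result


def _write_artifacts(
    result: PipelineResult,
    outdir: Path,
    reference: np.ndarray,
    sample: np.ndarray,
    write_genomes: bool,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    sim = result.config.sim
    dio.write_truth_bed(result.truth, outdir / "truth.bed")
    dio.write_pairs_tsv(result.alignments, outdir / "alignments.tsv")
    dio.write_bed(result.calls, outdir / "calls.bed")
    dio.write_bed(result.trimmed_calls, outdir / "trimmed.bed")
    dio.write_bedgraph(result.coverage, outdir / "coverage.bedgraph")
    if write_genomes:
        dio.write_fasta({sim.chrom: reference}, outdir / "reference.fa")
        dio.write_fasta({sim.chrom: sample}, outdir / "sample.fa")
    audit = pd.DataFrame(
        {
            "chrom": [r.original.chrom for r in result.trim_results],
            "start": [r.original.start for r in result.trim_results],
            "end": [r.original.end for r in result.trim_results],
            "trim_up": [r.trim_up for r in result.trim_results],
            "trim_down": [r.trim_down for r in result.trim_results],
            "status": ["removed" if r.removed else "kept" for r in result.trim_results],
        }
    )
    audit.to_csv(outdir / "trim_audit.tsv", sep="\t", index=False)
    summary_frame(result).to_csv(outdir / "summary.tsv", sep="\t", index=False)


def summary_frame(result: PipelineResult) -> pd.DataFrame:
    """One-row-per-call-set summary table (raw vs trimmed)."""
    rows = []
    for label, summ in (
        ("raw", result.raw_summary),
        ("trimmed", result.trimmed_summary),
    ):
        rows.append(
            {
                "call_set": label,
                "n_truth": summ.n_truth,
                "n_calls": summ.n_calls,
                "n_correct": summ.n_correct,
                "recall": summ.recall,
                "precision": summ.precision,
                "up_q25": summ.upstream_quartiles[0],
                "up_median": summ.upstream_quartiles[1],
                "up_q75": summ.upstream_quartiles[2],
                "down_q25": summ.downstream_quartiles[0],
                "down_median": summ.downstream_quartiles[1],
                "down_q75": summ.downstream_quartiles[2],
                "n_covering": summ.n_covering,
            }
        )
    return pd.DataFrame(rows)


def sweep_trim_params(
    result: PipelineResult,
    ks: Sequence[int] = (1, 2, 3, 4, 5),
    fs: Sequence[float] = tuple(f / 10 for f in range(1, 11)),
) -> pd.DataFrame:
    """Re-trim one run's calls over a grid of (k, f) settings.

    Reuses the run's coverage track and raw calls, so the sweep isolates
    the effect of the trimming thresholds.  Returns one row per (k, f)
    with the median upstream difference before and after trimming and the
    removed-call count.
    """
    rows = []
    for k in ks:
        for f in fs:
            params = replace(result.config.trim, k=int(k), f=float(f))
            res = trim_calls(result.calls, result.coverage, params)
            trimmed = [r.trimmed for r in res if r.trimmed is not None]
            records = match_calls(trimmed, result.truth)
            comp = compare_before_after(result.raw_records, records, "upstream")
            rows.append(
                {
                    "k": int(k),
                    "f": float(f),
                    "n_trimmed": sum(1 for r in res if r.trim_up or r.trim_down),
                    "n_removed": sum(1 for r in res if r.removed),
                    "median_up_before": comp.median_before,
                    "median_up_after": comp.median_after,
                    "fraction_improved": comp.fraction_improved,
                    "fraction_overtrimmed": comp.fraction_overtrimmed,
                }
            )
    return pd.DataFrame(rows)
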