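"""End-to-end per-embryo and cohort analysis orchestration.

``run_embryo`` chains count -> GC-correct -> normalise -> segment -> call
-> classify -> format for one sample and optionally writes a text report,
a per-bin profile table and a genome-wide copy-number plot. ``run_cohort``
maps ``run_embryo`` over a sample manifest and emits cohort-level tables
(classification x indication counts, clinical outcome comparisons, mtDNA
group comparison).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage, io as esio, karyotype as kt, mtdna, segmentation as seg
from .clinical import CohortSummary, OutcomeTable, aggregate_cohort, build_outcome_tables
from .exceptions import EmbryoScreenError
from .genome import GenomeModel

logger = logging.getLogger("embryoscreen")

__all__ = [
    "PipelineConfig",
    "EmbryoResult",
    "analyze_profile",
    "run_embryo",
    "run_cohort",
    "StageError",
]


class StageError(EmbryoScreenError):
    """Wraps a stage failure with the stage name and sample id."""

    def __init__(self, stage: str, sample_id: str, cause: Exception):
        super().__init__(f"[{stage}] sample {sample_id}: {cause}")
        self.stage = stage
        self.sample_id = sample_id
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    bin_size: int = 1_000_000
    read_length: int = 50
    gc_method: str = "auto"
    loess_span: float = 0.3
    segmentation: seg.SegmentationParams = field(
        default_factory=seg.SegmentationParams
    )
    min_cnv_length: int = 1_000_000
    whole_chrom_fraction: float = 0.9
    seed: int = 0
    write_plots: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = seg.SegmentationParams(**d["segmentation"])
        return cls(**d)


@dataclass
class EmbryoResult:
    """Complete per-embryo analysis outcome."""

    sample_id: str
    sex: str
    calls: list[kt.CnvCall]
    classification: str
    karyotype_strings: list[str]
    mito_ratio: float
    mito_fraction_covered: float
    profile: coverage.BinProfile = field(repr=False)
    segments: dict = field(repr=False, default=None)
    thresholds: tuple[float, float] = (float("nan"), float("nan"))


def analyze_profile(
    profile: coverage.BinProfile,
    genome: GenomeModel,
    config: PipelineConfig,
    seed: int | None = None,
) -> EmbryoResult:
    """Run correction, segmentation, calling and classification on a
    raw-count profile."""
    sid = profile.sample_id
    t0 = time.perf_counter()
    try:
        profile = coverage.gc_correct(
            profile, genome, method=config.gc_method, span=config.loess_span
        )
        profile = coverage.normalize_cn(profile, genome)
    except Exception as exc:
        raise StageError("gc_correct/normalize", sid, exc) from exc
    try:
        segments = seg.segment_profile(
            profile,
            genome,
            config.segmentation,
            seed=config.seed if seed is None else seed,
        )
        thresholds = seg.dynamic_thresholds(profile, config.segmentation)
    except Exception as exc:
        raise StageError("segmentation", sid, exc) from exc
    try:
        sex = kt.infer_sex(profile, genome)
        calls = kt.call_cnvs(
            segments,
            thresholds,
            genome,
            min_cnv_length=config.min_cnv_length,
            whole_chrom_fraction=config.whole_chrom_fraction,
            sex=sex,
            annotate=genome.cytobands is not None,
        )
        classification = kt.classify(calls)
        strings = (
            [kt.format_call(c, genome) for c in calls]
            if genome.cytobands is not None
            else []
        )
    except Exception as exc:
        raise StageError("calling", sid, exc) from exc
    try:
        ratio, frac = coverage.mito_stats(profile)
    except EmbryoScreenError:
        ratio, frac = float("nan"), float("nan")
    logger.info(
        "sample %s analysed in %.2fs: %s, %d calls, %d reads dropped",
        sid, time.perf_counter() - t0, classification, len(calls),
        profile.dropped_reads,
    )
    return EmbryoResult(
        sample_id=sid,
        sex=sex,
        calls=calls,
        classification=classification,
        karyotype_strings=strings,
        mito_ratio=ratio,
        mito_fraction_covered=frac,
        profile=profile,
        segments=segments,
        thresholds=thresholds,
    )


def run_embryo(
    reads,
    genome: GenomeModel,
    config: PipelineConfig = PipelineConfig(),
    sample_id: str = "sample",
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> EmbryoResult:
    """Analyse one embryo from read positions (DataFrame or file path)."""
    if isinstance(reads, (str, Path)):
        try:
            reads = esio.read_reads(reads)
        except Exception as exc:
            raise StageError("count_reads", sample_id, exc) from exc
    try:
        profile = coverage.count_reads(
            reads, genome, sample_id=sample_id, read_length=config.read_length
        )
    except Exception as exc:
        raise StageError("count_reads", sample_id, exc) from exc
    result = analyze_profile(profile, genome, config, seed=seed)
    if outdir is not None:
        write_embryo_outputs(result, genome, config, Path(outdir))
    return result


def write_embryo_outputs(
    result: EmbryoResult, genome: GenomeModel, config: PipelineConfig, outdir: Path
) -> None:
    """Write report.txt, bins.tsv, calls.tsv, params.json and the CN plot."""
    outdir.mkdir(parents=True, exist_ok=True)
    sid = result.sample_id
    prof = result.profile

    bins = genome.bin_table()
    bins["raw"] = prof.raw_counts
    bins["corrected"] = np.round(prof.gc_corrected, 4)
    bins["cn_ratio"] = np.round(prof.cn_ratio, 4)
    bins.to_csv(outdir / f"{sid}.bins.tsv", sep="\t", index=False)

    rows = []
    for c, s in zip(result.calls, result.karyotype_strings or [None] * len(result.calls)):
        rows.append(
            {
                "chrom": c.chrom, "start_bp": c.start_bp, "end_bp": c.end_bp,
                "copy_number": c.copy_number, "scope": c.scope,
                "length_bp": c.length_bp, "mean_cn": round(c.mean_cn, 4),
                "band_start": c.band_start, "band_end": c.band_end,
                "seq_string": s,
            }
        )
    pd.DataFrame(
        rows,
        columns=["chrom", "start_bp", "end_bp", "copy_number", "scope",
                 "length_bp", "mean_cn", "band_start", "band_end", "seq_string"],
    ).to_csv(outdir / f"{sid}.calls.tsv", sep="\t", index=False)

    lines = [
        f"sample\t{sid}",
        f"classification\t{result.classification}",
        f"sex\t{result.sex}",
        f"mito_ratio\t{result.mito_ratio:.4f}",
        f"mito_fraction_covered\t{result.mito_fraction_covered:.4f}",
        f"gain_cut\t{result.thresholds[0]:.4f}",
        f"loss_cut\t{result.thresholds[1]:.4f}",
        f"n_reads_total\t{prof.n_reads_total}",
        f"dropped_reads\t{prof.dropped_reads}",
        "calls:",
    ]
    lines += [f"  {s}" for s in result.karyotype_strings] or ["  (none)"]
    (outdir / f"{sid}.report.txt").write_text("\n".join(lines) + "\n")

    with open(outdir / f"{sid}.params.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)

    if config.write_plots:
        plot_profile(result, genome, outdir / f"{sid}.cn.png")


def plot_profile(result: EmbryoResult, genome: GenomeModel, path: Path) -> None:
    """Genome-wide copy-number scatter with segment means, digital-karyotype
    style: one panel, chromosomes concatenated and delimited."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prof = result.profile
    fig, ax = plt.subplots(figsize=(12, 3.2))
    x = np.arange(genome.n_bins)
    ax.scatter(x, prof.cn_ratio, s=4, c="#555555", alpha=0.6, linewidths=0)
    offset = 0
    for name, _ in genome.chromosomes:
        sl = genome.chrom_slice(name)
        for s in (result.segments or {}).get(name, []):
            ax.hlines(s.mean_cn, sl.start + s.start_bin, sl.start + s.end_bin,
                      colors="#d62728", linewidths=2)
        ax.axvline(sl.stop - 0.5, color="#bbbbbb", lw=0.5)
        ax.text((sl.start + sl.stop) / 2, 4.6, GenomeModel.display_name(name),
                ha="center", fontsize=7)
        offset = sl.stop
    for y in result.thresholds:
        ax.axhline(y, color="#1f77b4", lw=0.8, ls="--")
    ax.set_ylim(-0.2, 5)
    ax.set_xlim(0, offset)
    ax.set_ylabel("copy-number ratio")
    ax.set_title(f"{result.sample_id}: {result.classification}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_cohort(
    manifest: pd.DataFrame,
    genome: GenomeModel,
    config: PipelineConfig = PipelineConfig(),
    clinical_counts: tuple[dict, dict] | None = None,
    outdir: str | Path | None = None,
    strict: bool = False,
) -> dict:
    """Analyse a cohort manifest and aggregate cohort-level statistics.

    *manifest* needs columns ``sample_id``, ``reads`` (path or DataFrame)
    and ``stratum``. Failed samples are skipped (listed in the returned
    ``skipped``) unless *strict*. Returns a dict with ``results``,
    ``summary`` (CohortSummary), ``mtdna`` (comparison or None) and
    ``outcomes`` (list of OutcomeTable or None).
    """
    if strict and len(manifest) == 0:
        raise EmbryoScreenError("empty manifest in strict mode")
    results, strata, skipped = [], [], []
    for _, row in manifest.iterrows():
        sid = str(row["sample_id"])
        try:
            res = run_embryo(
                row["reads"], genome, config, sample_id=sid,
                outdir=Path(outdir) / sid if outdir else None,
            )
            results.append(res)
            strata.append(row.get("stratum", "all"))
        except (EmbryoScreenError, OSError) as exc:
            if strict:
                raise
            logger.warning("skipping sample %s: %s", sid, exc)
            skipped.append({"sample_id": sid, "error": str(exc)})
    summary = aggregate_cohort(results, strata) if results else None
    try:
        comparison = mtdna.compare_groups(results) if results else None
    except EmbryoScreenError:
        comparison = None
    outcomes = None
    if clinical_counts is not None:
        outcomes = build_outcome_tables(*clinical_counts)
    if outdir is not None:
        _write_cohort_outputs(Path(outdir), summary, outcomes, comparison, skipped)
    return {
        "results": results,
        "summary": summary,
        "mtdna": comparison,
        "outcomes": outcomes,
        "skipped": skipped,
    }


def _write_cohort_outputs(outdir, summary, outcomes, comparison, skipped):
    outdir.mkdir(parents=True, exist_ok=True)
    if summary is not None:
        summary.counts.to_csv(outdir / "cohort_classification.tsv", sep="\t")
        summary.percentages.round(1).to_csv(
            outdir / "cohort_classification_pct.tsv", sep="\t"
        )
    if outcomes is not None:
        rows = [
            {
                "measure": t.label, "rate1_pct": round(t.rate1, 2),
                "rate2_pct": round(t.rate2, 2),
                "pooled_pct": round(t.pooled_rate, 2),
                "chi2": None if t.chi2 is None else round(t.chi2, 4),
                "p_value": None if t.p_value is None else round(t.p_value, 3),
            }
            for t in outcomes
        ]
        pd.DataFrame(rows).to_csv(outdir / "clinical_outcomes.tsv", sep="\t",
                                  index=False)
    if comparison is not None:
        (outdir / "mtdna_comparison.txt").write_text(
            f"n_euploid\t{len(comparison.group_euploid)}\n"
            f"n_abnormal\t{len(comparison.group_abnormal)}\n"
            f"U\t{comparison.U}\np_value\t{comparison.p_value:.6g}\n"
            f"direction\t{comparison.direction}\n"
        )
    if skipped:
        pd.DataFrame(skipped).to_csv(outdir / "skipped.tsv", sep="\t", index=False)
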