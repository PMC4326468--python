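"""Bin counts, GC/WGA bias correction and copy-number normalisation.

Shallow single-end sequencing of whole-genome-amplified (WGA) material
yields read counts whose expectation depends strongly on local GC content.
This module turns aligned read start positions into fixed-width bin counts,
removes the GC trend by dividing each bin by a fitted count-vs-GC curve
(LOESS by default, GC-decile medians on tiny genomes), and rescales to a
copy-number ratio where the autosomal median is exactly 2.0 (diploid).

Reads on the mitochondrial contig are kept off the bin grid; their mean
depth relative to the nuclear genome (``ChrM_depth / Mean_depth``) is the
sample's relative mtDNA copy number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import InputMismatchError, NoSignalError
from .genome import GenomeModel

__all__ = ["BinProfile", "count_reads", "gc_correct", "normalize_cn", "mito_stats"]

#: bins-per-genome below which the GC fit falls back to decile medians
LOESS_MIN_BINS = 200

#: robust scale factor: MAD * 1.4826 estimates sigma under normality
MAD_SCALE = 1.4826


@dataclass
class BinProfile:
    """Per-bin coverage profile of one embryo sample.

    ``raw_counts``, ``gc_corrected`` and ``cn_ratio`` are aligned with the
    genome's concatenated bin grid. ``cn_ratio`` is scaled so that the
    autosomal median equals 2.0; ``sample_mad`` is the scaled median
    absolute deviation of autosomal ``cn_ratio`` (robust noise estimate).
    """

    sample_id: str
    raw_counts: np.ndarray
    gc_corrected: np.ndarray | None = None
    cn_ratio: np.ndarray | None = None
    sample_median: float = float("nan")
    sample_mad: float = float("nan")
    n_reads_total: int = 0
    genome_mean_depth: float = 0.0
    mito_mean_depth: float = 0.0
    mito_fraction_covered: float = 0.0
    mito_read_count: int = 0
    dropped_reads: int = 0
    read_length: int = 50


def count_reads(
    reads: pd.DataFrame,
    genome: GenomeModel,
    sample_id: str = "sample",
    read_length: int = 50,
    unknown_chrom_tolerance: float = 0.01,
) -> BinProfile:
    """Assign read start positions to genome bins.

    Reads on the mitochondrial contig are tallied separately into the mito
    depth statistics; reads on unknown contigs or beyond chromosome ends
    are dropped and counted. If the unknown-contig fraction exceeds
    *unknown_chrom_tolerance* the input is rejected as mismatched.
    """
    n_total = len(reads)
    chroms = reads["chrom"].to_numpy()
    starts = reads["start"].to_numpy(dtype=np.int64)

    counts = np.zeros(genome.n_bins, dtype=np.int64)
    dropped = 0

    mito_sel = chroms == genome.mito_name
    mito_starts = starts[mito_sel]
    in_mito = (mito_starts >= 0) & (mito_starts < genome.mito_length)
    dropped += int(np.sum(~in_mito))
    mito_starts = mito_starts[in_mito]

    known = set(genome.chrom_names)
    nuclear_sel = ~mito_sel
    unknown = 0
    for chrom in pd.unique(chroms[nuclear_sel]):
        sel = chroms == chrom
        if chrom not in known:
            unknown += int(sel.sum())
            continue
        pos = starts[sel]
        length = genome.lengths[chrom]
        ok = (pos >= 0) & (pos < length)
        dropped += int(np.sum(~ok))
        idx = pos[ok] // genome.bin_size
        sl = genome.chrom_slice(chrom)
        counts[sl] += np.bincount(idx, minlength=sl.stop - sl.start)

    if n_total and unknown / n_total > unknown_chrom_tolerance:
        raise InputMismatchError(
            f"{unknown}/{n_total} reads on contigs absent from the genome model"
        )
    dropped += unknown

    n_mito = int(mito_starts.size)
    mito_cov = 0.0
    if n_mito:
        covered = np.zeros(genome.mito_length, dtype=bool)
        ends = np.minimum(mito_starts + read_length, genome.mito_length)
        delta = np.zeros(genome.mito_length + 1, dtype=np.int64)
        np.add.at(delta, mito_starts, 1)
        np.add.at(delta, ends, -1)
        covered = np.cumsum(delta[:-1]) > 0
        mito_cov = float(covered.mean())

    n_nuclear = int(counts.sum())
    return BinProfile(
        sample_id=sample_id,
        raw_counts=counts,
        n_reads_total=n_total,
        genome_mean_depth=n_nuclear * read_length / genome.nuclear_length,
        mito_mean_depth=n_mito * read_length / genome.mito_length,
        mito_fraction_covered=mito_cov,
        mito_read_count=n_mito,
        dropped_reads=dropped,
        read_length=read_length,
    )


def _fit_gc_trend_loess(counts, gc, span):
    # local-linear LOESS with one "twicing" pass (refit the residuals and
    # add) to knock down curvature bias where the trend is strongly convex
    fit1 = lowess(counts, gc, frac=span, it=3, return_sorted=False)
    fit2 = lowess(counts - fit1, gc, frac=span, it=3, return_sorted=False)
    trend = fit1 + fit2
    xs, idx = np.unique(gc, return_index=True)
    ys = trend[idx]
    return lambda g: np.interp(g, xs, ys)  # nearest-edge beyond support


def _fit_gc_trend_stratified(counts, gc, n_strata=10):
    edges = np.quantile(gc, np.linspace(0, 1, n_strata + 1))
    edges = np.unique(edges)
    mids, meds = [], []
    which = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, len(edges) - 2)
    for s in range(len(edges) - 1):
        sel = which == s
        if sel.any():
            mids.append(gc[sel].mean())
            meds.append(np.median(counts[sel]))
    mids, meds = np.asarray(mids), np.asarray(meds)
    order = np.argsort(mids)
    mids, meds = mids[order], meds[order]
    return lambda g: np.interp(g, mids, meds)


def gc_correct(
    profile: BinProfile,
    genome: GenomeModel,
    method: str = "auto",
    span: float = 0.3,
) -> BinProfile:
    """Remove the GC-dependent WGA amplification trend from bin counts.

    Fits the count-vs-GC trend ``f`` on autosomal bins and divides every
    bin by ``f(gc)``, then rescales so total mass is preserved. ``method``
    is ``"loess"`` (local linear, robustified), ``"stratified"`` (GC-decile
    medians) or ``"auto"`` (LOESS unless the genome has fewer than
    ``LOESS_MIN_BINS`` bins). A degenerate GC track (all bins within 0.001)
    leaves counts unchanged with a warning.
    """
    counts = profile.raw_counts.astype(float)
    gc = genome.gc_per_bin
    auto = genome.autosomal_mask()
    if int(np.count_nonzero(counts[auto] > 0)) < 50:
        raise NoSignalError("need at least 50 autosomal bins with nonzero counts")

    if gc[auto].max() - gc[auto].min() < 1e-3:
        warnings.warn("degenerate GC track; GC correction is the identity")
        return replace(profile, gc_corrected=counts.copy())

    if method == "auto":
        method = "loess" if genome.n_bins >= LOESS_MIN_BINS else "stratified"
    if method == "loess":
        f = _fit_gc_trend_loess(counts[auto], gc[auto], span)
    elif method == "stratified":
        f = _fit_gc_trend_stratified(counts[auto], gc[auto])
    else:
        raise ValueError(f"unknown GC correction method {method!r}")

    trend = np.asarray(f(gc), dtype=float)
    floor = 1e-6 * max(counts[auto].mean(), 1.0)
    trend = np.maximum(trend, floor)
    corrected = counts / trend
    # rescale: sum(corrected) == sum(raw) (mass conservation convention)
    total = corrected.sum()
    if total > 0:
        corrected *= counts.sum() / total
    return replace(profile, gc_corrected=corrected)


def normalize_cn(profile: BinProfile, genome: GenomeModel) -> BinProfile:
    """Scale corrected counts to copy-number ratios (autosomal median = 2).

    Also computes the sample's robust noise level ``sample_mad`` as the
    1.4826-scaled median absolute deviation of autosomal ``cn_ratio``; sex
    chromosomes are excluded from both statistics so an XY sample's halved
    X signal cannot shift the baseline.
    """
    if profile.gc_corrected is None:
        raise ValueError("run gc_correct before normalize_cn")
    auto = genome.autosomal_mask()
    med = float(np.median(profile.gc_corrected[auto]))
    if med == 0:
        raise NoSignalError("autosomal median of corrected counts is zero")
    cn = 2.0 * profile.gc_corrected / med
    mad = MAD_SCALE * float(np.median(np.abs(cn[auto] - np.median(cn[auto]))))
    return replace(profile, cn_ratio=cn, sample_median=med, sample_mad=mad)


def mito_stats(profile: BinProfile) -> tuple[float, float]:
    """Relative mtDNA copy number and fraction of the mito contig covered.

    The ratio is mean mitochondrial depth over mean nuclear genome depth
    (``ChrM_depth / Mean_depth``); depth is reads x read_length / length.
    """
    if profile.genome_mean_depth == 0:
        raise NoSignalError("genome mean depth is zero; mtDNA ratio undefined")
    return (
        profile.mito_mean_depth / profile.genome_mean_depth,
        profile.mito_fraction_covered,
    )
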