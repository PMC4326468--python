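"""Synthetic genomes, karyotypes and shallow-WGS read simulation.

Stands in for the study's raw sequencing data: blastocyst trophectoderm
biopsies amplified by WGA and sequenced shallowly (single-end reads at
~0.13x nuclear depth; the mitochondrial contig nearly fully covered with
depth proportional to mtDNA copy number).

The simulator works at bin resolution: expected bin count is proportional
to (local copy number / 2) x a unimodal GC bias weight, realised counts
are negative-binomially overdispersed (the WGA signature), and read start
positions are then scattered uniformly within each bin. This per-bin
sampler has the same first and second moments at bin scale as a per-read
sampler and is orders of magnitude faster; positions are still emitted so
the full pipeline (binning included) is exercised end to end.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
children with fixed indices per component, so partial re-runs reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidKaryotypeError, InvalidSpecError
from .genome import GenomeModel
from .karyotype import (
    CLASS_BOTH,
    CLASS_EUPLOID,
    CLASS_IMBALANCED,
    CLASS_NUMERICAL,
    CLASSES,
)

__all__ = [
    "SyntheticGenomeSpec",
    "KaryotypeSpec",
    "ReadSimConfig",
    "SimulatedEmbryo",
    "default_genome_spec",
    "make_synthetic_genome",
    "simulate_reads",
    "simulate_bin_counts",
    "simulate_cohort",
    "gc_bias_weight",
]

#: study-scale constants the simulator is calibrated to
HUMAN_GENOME_BP = 3.1e9
STUDY_READS = 8.2e6  # mean reads per blastocyst at full human-genome scale


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Blueprint for a small human-like genome.

    GC varies smoothly along each chromosome (low-frequency sinusoid plus
    noise, clamped to [0.25, 0.65]); cytobands are generated per arm with
    a centromere at *centromere_fraction*, named ``p2, p1 | q1, q2, ...``.
    """

    autosome_lengths: tuple[int, ...]
    include_sex_chromosomes: bool = True
    x_length: int = 30_000_000
    y_length: int = 15_000_000
    mito_length: int = 16_569
    band_count_per_chromosome: int = 8
    centromere_fraction: float = 0.4
    gc_amplitude: float = 0.12
    gc_period_bins: float = 32.0
    gc_noise_sd: float = 0.02

    @property
    def n_autosomes(self) -> int:
        return len(self.autosome_lengths)

    def chromosome_list(self) -> tuple[tuple[str, int], ...]:
        chroms = [(f"chr{i + 1}", int(l)) for i, l in enumerate(self.autosome_lengths)]
        if self.include_sex_chromosomes:
            chroms += [("chrX", int(self.x_length)), ("chrY", int(self.y_length))]
        return tuple(chroms)


def default_genome_spec() -> SyntheticGenomeSpec:
    """A ~300 Mb genome: 8 autosomes (45 down to 24 Mb) plus X and Y."""
    return SyntheticGenomeSpec(
        autosome_lengths=tuple(45_000_000 - 3_000_000 * i for i in range(8))
    )


def _make_bands(name: str, length: int, spec: SyntheticGenomeSpec) -> list[dict]:
    n = spec.band_count_per_chromosome
    if n < 2:
        raise InvalidSpecError("need at least 2 bands per chromosome")
    cen = int(round(spec.centromere_fraction * length))
    n_p = max(1, int(round(spec.centromere_fraction * n)))
    n_q = max(1, n - n_p)
    rows = []
    p_edges = np.linspace(0, cen, n_p + 1).round().astype(int)
    for k in range(n_p):
        rows.append(
            {"chrom": name, "start": int(p_edges[k]), "end": int(p_edges[k + 1]),
             "band": f"p{n_p - k}"}
        )
    q_edges = np.linspace(cen, length, n_q + 1).round().astype(int)
    for k in range(n_q):
        rows.append(
            {"chrom": name, "start": int(q_edges[k]), "end": int(q_edges[k + 1]),
             "band": f"q{k + 1}"}
        )
    return rows


def make_synthetic_genome(
    spec: SyntheticGenomeSpec, seed: int, bin_size: int = 1_000_000
) -> GenomeModel:
    """Generate a genome model with GC track and cytobands; deterministic."""
    chroms = spec.chromosome_list()
    for name, length in chroms:
        if length < 10 * bin_size:
            raise InvalidSpecError(
                f"{name} has {length} bp; need at least 10 bins of {bin_size}"
            )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gc_parts, band_rows = [], []
    for name, length in chroms:
        nb = -(-length // bin_size)
        phase = rng.uniform(0, 2 * np.pi)
        k = np.arange(nb)
        gc = (
            0.45
            + spec.gc_amplitude * np.sin(2 * np.pi * k / spec.gc_period_bins + phase)
            + rng.normal(0, spec.gc_noise_sd, nb)
        )
        gc_parts.append(np.clip(gc, 0.25, 0.65))
        band_rows.extend(_make_bands(name, length, spec))
    return GenomeModel(
        chromosomes=chroms,
        bin_size=bin_size,
        gc_per_bin=np.concatenate(gc_parts),
        cytobands=pd.DataFrame(band_rows),
        mito_name="chrM",
        mito_length=spec.mito_length,
    )


@dataclass(frozen=True)
class KaryotypeSpec:
    """True chromosomal state of one simulated embryo.

    ``events`` are non-overlapping ``(chrom, start_bp, end_bp, copy_number)``
    tuples with integer copy number in {0, 1, 3, 4}; background is diploid
    on autosomes and follows ``sex`` on X/Y. ``mito_copy_factor``
    multiplies the mitochondrial depth relative to the euploid baseline.
    """

    events: tuple[tuple[str, int, int, int], ...] = ()
    sex: str = "XX"
    mito_copy_factor: float = 1.0

    def validate(self, genome: GenomeModel) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, cn in self.events:
            if chrom not in genome.lengths:
                raise InvalidKaryotypeError(f"unknown chromosome {chrom!r}")
            if not (0 <= start < end <= genome.lengths[chrom]):
                raise InvalidKaryotypeError(
                    f"event {chrom}:{start}-{end} outside chromosome bounds"
                )
            if cn not in (0, 1, 3, 4):
                raise InvalidKaryotypeError(f"copy number {cn} not in {{0,1,3,4}}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs[:-1], ivs[1:]):
                if s2 < e1:
                    raise InvalidKaryotypeError(f"overlapping events on {chrom}")
        if self.sex not in ("XX", "XY"):
            raise InvalidKaryotypeError(f"sex must be XX or XY, got {self.sex!r}")
        if self.mito_copy_factor <= 0:
            raise InvalidKaryotypeError("mito_copy_factor must be positive")


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation parameters.

    ``n_reads=None`` scales the study's 8.2 million reads per blastocyst
    to the synthetic genome's size, preserving per-bin depth (~2,700 reads
    per 1 Mb bin). ``overdispersion`` d gives per-bin variance
    mu + d*mu^2 (d=0 is Poisson); the default 0.0025 adds ~5% extra CV,
    a WGA-like noise floor. The GC bias weight is quadratic, peaking at
    ``gc_bias_peak``: w(gc) = max(0.1, 1 - curvature*(gc - peak)^2).
    ``mito_mean_depth_ratio`` is the expected ChrM_depth/Mean_depth of a
    euploid baseline sample.
    """

    n_reads: int | None = None
    read_length: int = 50
    gc_bias_peak: float = 0.45
    gc_bias_curvature: float = 6.0
    flat_gc_bias: bool = False
    overdispersion: float = 0.0025
    mito_mean_depth_ratio: float = 100.0
    seed: int = 0

    def resolved_n_reads(self, genome: GenomeModel) -> int:
        if self.n_reads is not None:
            if self.n_reads <= 0:
                raise InvalidSpecError("n_reads must be positive")
            return int(self.n_reads)
        return int(round(STUDY_READS * genome.nuclear_length / HUMAN_GENOME_BP))


def gc_bias_weight(gc, cfg: ReadSimConfig) -> np.ndarray:
    """Relative sampling weight of a bin as a function of its GC fraction."""
    gc = np.asarray(gc, dtype=float)
    if cfg.flat_gc_bias:
        return np.ones_like(gc)
    w = 1.0 - cfg.gc_bias_curvature * (gc - cfg.gc_bias_peak) ** 2
    return np.maximum(w, 0.1)


def _bin_copy_number(genome: GenomeModel, karyotype: KaryotypeSpec) -> np.ndarray:
    """Effective copy number per bin (partial bins get the coverage-weighted
    mixture of event and background copy number)."""
    cn = np.empty(genome.n_bins, dtype=float)
    for name, length in genome.chromosomes:
        base = 2.0
        disp = GenomeModel.display_name(name)
        if disp == "X":
            base = 2.0 if karyotype.sex == "XX" else 1.0
        elif disp == "Y":
            base = 0.0 if karyotype.sex == "XX" else 1.0
        cn[genome.chrom_slice(name)] = base
    bs = genome.bin_size
    for chrom, start, end, ev_cn in karyotype.events:
        sl = genome.chrom_slice(chrom)
        length = genome.lengths[chrom]
        nb = sl.stop - sl.start
        bin_starts = np.arange(nb) * bs
        bin_ends = np.minimum(bin_starts + bs, length)
        overlap = np.clip(
            np.minimum(bin_ends, end) - np.maximum(bin_starts, start), 0, None
        )
        frac = overlap / (bin_ends - bin_starts)
        base = cn[sl]
        cn[sl] = base * (1 - frac) + ev_cn * frac
    return cn


def simulate_bin_counts(
    genome: GenomeModel,
    karyotype: KaryotypeSpec,
    cfg: ReadSimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Draw per-bin nuclear counts and a mitochondrial read count."""
    karyotype.validate(genome)
    n_reads = cfg.resolved_n_reads(genome)
    cn = _bin_copy_number(genome, karyotype)
    w = (cn / 2.0) * gc_bias_weight(genome.gc_per_bin, cfg)
    wsum = w.sum()
    if wsum <= 0:
        raise InvalidSpecError("all sampling weights are zero")
    mu = n_reads * w / wsum
    d = cfg.overdispersion
    if d > 0:
        r = 1.0 / d  # NB size: var = mu + mu^2 / r
        p = r / (r + mu)
        counts = np.where(mu > 0, rng.negative_binomial(r, np.minimum(p, 1.0)), 0)
    else:
        counts = rng.poisson(mu)
    # mitochondrial reads: depth ratio x euploid nuclear depth x copy factor
    depth = n_reads * cfg.read_length / genome.nuclear_length
    mito_mu = (
        cfg.mito_mean_depth_ratio
        * karyotype.mito_copy_factor
        * depth
        * genome.mito_length
        / cfg.read_length
    )
    n_mito = int(rng.poisson(mito_mu))
    return counts.astype(np.int64), n_mito


def simulate_reads(
    genome: GenomeModel, karyotype: KaryotypeSpec, cfg: ReadSimConfig
) -> pd.DataFrame:
    """Simulate aligned read start positions for one embryo.

    Returns a DataFrame with ``chrom`` and ``start`` columns (0-based),
    nuclear reads first, mitochondrial reads last; deterministic in
    ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    counts, n_mito = simulate_bin_counts(genome, karyotype, cfg, rng)
    bin_tab = genome.bin_table()
    starts_lo = bin_tab["start"].to_numpy()
    starts_hi = np.maximum(
        bin_tab["end"].to_numpy() - cfg.read_length, starts_lo + 1
    )
    reps = counts
    lo = np.repeat(starts_lo, reps)
    hi = np.repeat(starts_hi, reps)
    pos = rng.integers(lo, hi) if lo.size else np.empty(0, dtype=np.int64)
    chroms = np.repeat(bin_tab["chrom"].to_numpy(), reps)
    mito_hi = max(genome.mito_length - cfg.read_length, 1)
    mito_pos = rng.integers(0, mito_hi, size=n_mito)
    return pd.DataFrame(
        {
            "chrom": np.concatenate([chroms, np.full(n_mito, genome.mito_name)]),
            "start": np.concatenate([pos, mito_pos]).astype(np.int64),
        }
    )


# --------------------------------------------------------------------- cohort

#: four-way class frequencies of the sequencing arm of the study cohort
STUDY_CLASS_FREQUENCIES = {
    CLASS_EUPLOID: 198 / 454,
    CLASS_NUMERICAL: 85 / 454,
    CLASS_IMBALANCED: 127 / 454,
    CLASS_BOTH: 44 / 454,
}


@dataclass(frozen=True)
class SimulatedEmbryo:
    sample_id: str
    karyotype: KaryotypeSpec
    truth_class: str
    reads: pd.DataFrame = field(repr=False, compare=False, default=None)


def _draw_whole_chrom_event(genome, rng, used: set) -> tuple:
    autosomes = [n for n, _ in genome.chromosomes
                 if GenomeModel.display_name(n) not in ("X", "Y") and n not in used]
    chrom = str(rng.choice(autosomes))
    used.add(chrom)
    cn = int(rng.choice([1, 3]))
    return (chrom, 0, genome.lengths[chrom], cn)


def _draw_segmental_event(
    genome, rng, used: set, min_len: int, max_len: int
) -> tuple:
    autosomes = [n for n, _ in genome.chromosomes
                 if GenomeModel.display_name(n) not in ("X", "Y") and n not in used]
    chrom = str(rng.choice(autosomes))
    used.add(chrom)
    length = genome.lengths[chrom]
    # keep segmental events below 70% of the chromosome so they stay
    # sub-chromosomal at the caller's 90% whole-chromosome boundary
    hi = min(max_len, int(0.7 * length))
    lo = min(min_len, hi)
    ev_len = int(rng.integers(lo, hi + 1))
    if rng.random() < 0.5:  # terminal event (translocation-derivative-like)
        start = 0 if rng.random() < 0.5 else length - ev_len
    else:
        start = int(rng.integers(0, length - ev_len + 1))
    cn = int(rng.choice([1, 3]))
    return (chrom, start, start + ev_len, cn)


def draw_karyotype(
    truth_class: str,
    genome: GenomeModel,
    rng: np.random.Generator,
    min_event_bp: int = 10_000_000,
    max_event_bp: int = 80_000_000,
    mito_sigma: float = 0.5,
    mito_shift_abnormal: float = 1.3,
) -> KaryotypeSpec:
    """Draw a random karyotype realising the requested four-way class.

    Whole-chromosome events are full-length trisomies/monosomies; segmental
    events are 10-80 Mb (capped at 70% of the chromosome), terminally
    anchored half the time, mimicking unbalanced translocation derivatives.
    The mtDNA factor is lognormal with sigma ``mito_sigma`` around 1,
    shifted up by ``mito_shift_abnormal`` for abnormal embryos.
    """
    used: set = set()
    events = []
    if truth_class == CLASS_NUMERICAL:
        for _ in range(1 + int(rng.random() < 0.4)):
            events.append(_draw_whole_chrom_event(genome, rng, used))
    elif truth_class == CLASS_IMBALANCED:
        for _ in range(1 + int(rng.random() < 0.4)):
            events.append(
                _draw_segmental_event(genome, rng, used, min_event_bp, max_event_bp)
            )
    elif truth_class == CLASS_BOTH:
        events.append(_draw_whole_chrom_event(genome, rng, used))
        events.append(
            _draw_segmental_event(genome, rng, used, min_event_bp, max_event_bp)
        )
    elif truth_class != CLASS_EUPLOID:
        raise InvalidSpecError(f"unknown class {truth_class!r}")
    sex = "XX" if rng.random() < 0.5 else "XY"
    factor = float(np.exp(rng.normal(0.0, mito_sigma)))
    if truth_class != CLASS_EUPLOID:
        factor *= mito_shift_abnormal
    return KaryotypeSpec(events=tuple(events), sex=sex, mito_copy_factor=factor)


def simulate_cohort(
    n_embryos: int,
    class_frequencies: dict | None,
    genome: GenomeModel,
    cfg: ReadSimConfig,
    seed: int,
    with_reads: bool = True,
    **karyotype_kwargs,
) -> list[SimulatedEmbryo]:
    """Simulate a labelled embryo cohort.

    Classes are drawn i.i.d. from *class_frequencies* (default: the study
    cohort's observed four-way distribution). Each embryo gets its own
    seed derived from *seed*, so embryo k is reproducible in isolation.
    """
    freqs = dict(class_frequencies or STUDY_CLASS_FREQUENCIES)
    probs = np.array([freqs.get(c, 0.0) for c in CLASSES], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise InvalidSpecError("class frequencies must sum to 1")
    children = np.random.SeedSequence(seed).spawn(n_embryos + 1)
    label_rng = np.random.default_rng(children[0])
    labels = label_rng.choice(len(CLASSES), size=n_embryos, p=probs)
    embryos = []
    for k in range(n_embryos):
        rng = np.random.default_rng(children[k + 1])
        truth = CLASSES[labels[k]]
        kar = draw_karyotype(truth, genome, rng, **karyotype_kwargs)
        reads = None
        if with_reads:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            reads = simulate_reads(genome, kar, replace(cfg, seed=sub_seed))
        embryos.append(
            SimulatedEmbryo(
                sample_id=f"E{k + 1:03d}", karyotype=kar, truth_class=truth,
                reads=reads,
            )
        )
    return embryos
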