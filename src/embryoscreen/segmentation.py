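"""Binary-segmentation breakpoint detection and dynamic calling thresholds.

Each chromosome's per-bin copy-number series is split recursively at the
position maximising a t-like mean-shift statistic

    T(i) = (mean(left) - mean(right)) / (s * sqrt(1/i + 1/(n-i)))

with ``s`` the pooled within-side standard deviation. A split is accepted
when its |T| exceeds the (1 - alpha) quantile of the same statistic on
within-segment permutations of the values; recursion stops on rejection,
on the minimum-segment-size floor, or at the depth cap. With
``n_permutations == 0`` acceptance is deterministic (any strictly positive
statistic splits), which is only meaningful on noise-free input.

The per-sample calling thresholds adapt to measured noise:

    cut = 2 +/- max(threshold_floor, threshold_k * MAD / sqrt(min_seg_bins))

so noisy WGA samples need a larger deviation before a segment is called,
while the absolute floor keeps sub-mosaic wobble from ever being called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import BinProfile
from .genome import GenomeModel

__all__ = [
    "Segment",
    "SegmentationParams",
    "best_split",
    "segment_chromosome",
    "segment_profile",
    "dynamic_thresholds",
]


@dataclass(frozen=True)
class Segment:
    """A maximal run of bins with constant estimated copy number."""

    chrom: str
    start_bin: int  # half-open bin-index range within the chromosome
    end_bin: int
    start_bp: int
    end_bp: int
    mean_cn: float

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass(frozen=True)
class SegmentationParams:
    min_seg_bins: int = 3
    alpha: float = 0.01
    n_permutations: int = 1000
    max_depth: int = 20
    threshold_k: float = 3.0
    threshold_floor: float = 0.4

    def __post_init__(self):
        if self.min_seg_bins < 2:
            raise ValueError("min_seg_bins must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _split_stats(values: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """|T(i)| for every admissible split i in [m, n-m]; returns (i, |T|)."""
    n = values.size
    i = np.arange(m, n - m + 1)
    cs = np.cumsum(values)
    css = np.cumsum(values * values)
    total, total_sq = cs[-1], css[-1]
    sum_l = cs[i - 1]
    sumsq_l = css[i - 1]
    nl, nr = i, n - i
    mean_l = sum_l / nl
    mean_r = (total - sum_l) / nr
    sse = (sumsq_l - nl * mean_l**2) + ((total_sq - sumsq_l) - nr * mean_r**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.sqrt(np.maximum(sse, 0.0) / (n - 2)) if n > 2 else np.zeros_like(mean_l)
        t = np.abs(mean_l - mean_r) / (s * np.sqrt(1.0 / nl + 1.0 / nr))
    diff = np.abs(mean_l - mean_r)
    scale = max(np.abs(values).max(), 1.0)
    zero_s = ~(s > 1e-12 * scale)
    t = np.where(zero_s, np.where(diff > 1e-12 * scale, np.inf, 0.0), t)
    return i, t


def best_split(values: np.ndarray, min_seg_bins: int = 3) -> tuple[int, float]:
    """Best single split of *values*: (left-size i, |T| statistic).

    Ties are broken toward the smallest i; a constant series returns
    statistic 0 at i = min_seg_bins.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2 * min_seg_bins:
        raise ValueError(f"need at least {2 * min_seg_bins} values, got {n}")
    i, t = _split_stats(values, min_seg_bins)
    k = int(np.argmax(t))  # argmax returns the first maximiser -> smallest i
    stat = float(t[k])
    if stat == 0.0:
        return min_seg_bins, 0.0
    return int(i[k]), stat


def _permutation_quantile(
    values: np.ndarray, m: int, params: SegmentationParams, rng: np.random.Generator
) -> float:
    """(1 - alpha) quantile of max|T| over within-segment permutations."""
    n = values.size
    perms = np.tile(values, (params.n_permutations, 1))
    perms = rng.permuted(perms, axis=1)
    i = np.arange(m, n - m + 1)
    cs = np.cumsum(perms, axis=1)
    css = np.cumsum(perms * perms, axis=1)
    total = cs[:, -1:]
    total_sq = css[:, -1:]
    sum_l = cs[:, i - 1]
    sumsq_l = css[:, i - 1]
    nl = i[None, :].astype(float)
    nr = n - nl
    mean_l = sum_l / nl
    mean_r = (total - sum_l) / nr
    sse = (sumsq_l - nl * mean_l**2) + ((total_sq - sumsq_l) - nr * mean_r**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.sqrt(np.maximum(sse, 0.0) / (n - 2))
        t = np.abs(mean_l - mean_r) / (s * np.sqrt(1.0 / nl + 1.0 / nr))
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf)
    null = t.max(axis=1)
    return float(np.quantile(null, 1.0 - params.alpha))


def _window_stats(rows: np.ndarray, m: int) -> np.ndarray:
    """Max double-cut statistic per row: best interior window [i, j) vs the
    rest, i >= m, j <= n - m, window length >= m. Used by the circular
    refinement that catches events embedded mid-segment, which a single
    split cannot separate."""
    rows = np.atleast_2d(rows)
    n = rows.shape[1]
    cs = np.cumsum(rows, axis=1)
    css = np.cumsum(rows * rows, axis=1)
    cs = np.concatenate([np.zeros((rows.shape[0], 1)), cs], axis=1)
    css = np.concatenate([np.zeros((rows.shape[0], 1)), css], axis=1)
    total = cs[:, -1:]
    total_sq = css[:, -1:]
    best = np.zeros(rows.shape[0])
    scale = max(np.abs(rows).max(), 1.0)
    for L in range(m, n - 2 * m + 1):
        i = np.arange(m, n - m - L + 1)
        if i.size == 0:
            continue
        w = cs[:, i + L] - cs[:, i]
        wsq = css[:, i + L] - css[:, i]
        n_in, n_out = float(L), float(n - L)
        mean_in = w / n_in
        mean_out = (total - w) / n_out
        sse = (wsq - n_in * mean_in**2) + (
            (total_sq - wsq) - n_out * mean_out**2
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.sqrt(np.maximum(sse, 0.0) / (n - 2))
            t = np.abs(mean_in - mean_out) / (s * np.sqrt(1 / n_in + 1 / n_out))
        diff = np.abs(mean_in - mean_out)
        zero_s = ~(s > 1e-12 * scale)
        t = np.where(zero_s, np.where(diff > 1e-12 * scale, np.inf, 0.0), t)
        best = np.maximum(best, t.max(axis=1))
    return best


def _best_window(values: np.ndarray, m: int) -> tuple[int, int, float]:
    """Location (i, j) and value of the best double-cut statistic."""
    n = values.size
    cs = np.concatenate([[0.0], np.cumsum(values)])
    css = np.concatenate([[0.0], np.cumsum(values * values)])
    total, total_sq = cs[-1], css[-1]
    scale = max(np.abs(values).max(), 1.0)
    best = (m, 2 * m, 0.0)
    for L in range(m, n - 2 * m + 1):
        i = np.arange(m, n - m - L + 1)
        if i.size == 0:
            continue
        w = cs[i + L] - cs[i]
        wsq = css[i + L] - css[i]
        mean_in = w / L
        mean_out = (total - w) / (n - L)
        sse = (wsq - L * mean_in**2) + ((total_sq - wsq) - (n - L) * mean_out**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.sqrt(np.maximum(sse, 0.0) / (n - 2))
            t = np.abs(mean_in - mean_out) / (s * np.sqrt(1 / L + 1 / (n - L)))
        diff = np.abs(mean_in - mean_out)
        zero_s = ~(s > 1e-12 * scale)
        t = np.where(zero_s, np.where(diff > 1e-12 * scale, np.inf, 0.0), t)
        k = int(np.argmax(t))
        if t[k] > best[2]:
            best = (int(i[k]), int(i[k]) + L, float(t[k]))
    return best


def _double_cut_accepted(values, params, rng) -> tuple[int, int] | None:
    n = values.size
    if n < 3 * params.min_seg_bins:
        return None
    i, j, stat = _best_window(values, params.min_seg_bins)
    if stat == 0.0:
        return None
    if not np.isinf(stat):
        perms = np.tile(values, (params.n_permutations, 1))
        perms = rng.permuted(perms, axis=1)
        null = _window_stats(perms, params.min_seg_bins)
        if stat <= np.quantile(null, 1.0 - params.alpha):
            return None
    return i, j


def _recurse(values, offset, params, rng, depth, breaks):
    n = values.size
    if n < 2 * params.min_seg_bins or depth >= params.max_depth:
        return
    i, stat = best_split(values, params.min_seg_bins)
    if params.n_permutations == 0:
        # deterministic mode: accept any strictly positive statistic
        if stat == 0.0:
            return
    elif stat == 0.0 or (
        not np.isinf(stat)
        and stat <= _permutation_quantile(values, params.min_seg_bins, params, rng)
    ):
        # single split rejected: a shift embedded mid-segment can still be
        # present (it attenuates the single-split statistic); try the
        # circular double-cut test before declaring the segment flat
        window = _double_cut_accepted(values, params, rng)
        if window is None:
            return
        a, b = window
        breaks.append(offset + a)
        breaks.append(offset + b)
        _recurse(values[:a], offset, params, rng, depth + 1, breaks)
        _recurse(values[a:b], offset + a, params, rng, depth + 1, breaks)
        _recurse(values[b:], offset + b, params, rng, depth + 1, breaks)
        return
    breaks.append(offset + i)
    _recurse(values[:i], offset, params, rng, depth + 1, breaks)
    _recurse(values[i:], offset + i, params, rng, depth + 1, breaks)


def segment_chromosome(
    values: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    seed: int | np.random.Generator = 0,
    chrom: str = "chr",
    bin_size: int = 1_000_000,
    chrom_length: int | None = None,
) -> list[Segment]:
    """Recursively segment one chromosome's cn series into constant runs."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    breaks: list[int] = []
    _recurse(values, 0, params, rng, 0, breaks)
    bounds = [0] + sorted(breaks) + [values.size]
    if chrom_length is None:
        chrom_length = values.size * bin_size
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        out.append(
            Segment(
                chrom=chrom,
                start_bin=a,
                end_bin=b,
                start_bp=a * bin_size,
                end_bp=min(b * bin_size, chrom_length),
                mean_cn=float(values[a:b].mean()),
            )
        )
    return out


def segment_profile(
    profile: BinProfile,
    genome: GenomeModel,
    params: SegmentationParams = SegmentationParams(),
    seed: int = 0,
) -> dict[str, list[Segment]]:
    """Segment every chromosome of a normalised profile independently."""
    if profile.cn_ratio is None:
        raise ValueError("run normalize_cn before segmentation")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(genome.chromosomes))
    out: dict[str, list[Segment]] = {}
    for (name, length), child in zip(genome.chromosomes, children):
        vals = profile.cn_ratio[genome.chrom_slice(name)]
        if vals.size < 2 * params.min_seg_bins:
            out[name] = [
                Segment(name, 0, vals.size, 0, length, float(vals.mean()))
            ]
            continue
        out[name] = segment_chromosome(
            vals,
            params,
            np.random.default_rng(child),
            chrom=name,
            bin_size=genome.bin_size,
            chrom_length=length,
        )
    return out


def dynamic_thresholds(
    profile: BinProfile, params: SegmentationParams = SegmentationParams()
) -> tuple[float, float]:
    """Per-sample (gain_cut, loss_cut) adapted to measured noise.

    The deviation term is the noise of a minimum-size segment mean
    (MAD / sqrt(min_seg_bins)) scaled by ``threshold_k``, floored at
    ``threshold_floor`` so quiet samples are not over-called.
    """
    mad = profile.sample_mad
    if not np.isfinite(mad):
        raise ValueError("sample_mad not computed; run normalize_cn first")
    dev = max(
        params.threshold_floor,
        params.threshold_k * mad / np.sqrt(params.min_seg_bins),
    )
    return 2.0 + dev, 2.0 - dev
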