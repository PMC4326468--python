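"""CNV calling, sex inference, embryo classification and call nomenclature.

Filtered segments become integer-copy-number calls at >= 1 Mb resolution.
Whole-chromosome calls (covering >= 90% of a chromosome by default) are
"numerical" aberrations; sub-chromosomal calls are "imbalanced" (segmental)
aberrations, and an embryo is classified as euploid / numerical /
imbalanced / numerical+imbalanced by which kinds of call it carries.

Calls are rendered in sequencing-karyotype nomenclature, e.g.::

    seq 2q31.3 -> qter(182458386-242690112)x1

with an arrow and en dash, cytoband labels at both ends (``pter``/``qter``
for terminal bands) and 1-based inclusive coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .coverage import BinProfile
from .exceptions import AnnotationError
from .genome import GenomeModel
from .segmentation import Segment

__all__ = [
    "CnvCall",
    "call_cnvs",
    "infer_sex",
    "classify",
    "format_call",
    "parse_call",
    "expected_cn",
]

CLASS_EUPLOID = "euploid"
CLASS_NUMERICAL = "numerical"
CLASS_IMBALANCED = "imbalanced"
CLASS_BOTH = "numerical+imbalanced"
CLASSES = (CLASS_EUPLOID, CLASS_NUMERICAL, CLASS_IMBALANCED, CLASS_BOTH)


@dataclass(frozen=True)
class CnvCall:
    chrom: str
    start_bp: int  # 0-based half-open internally
    end_bp: int
    copy_number: int
    scope: str  # "whole-chromosome" | "segmental"
    mean_cn: float = float("nan")
    band_start: str | None = None
    band_end: str | None = None

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def expected_cn(chrom: str, sex: str) -> float:
    """Baseline copy number of *chrom* given inferred sex.

    Autosomes are 2; X is 2/1 and Y is 0/1 for XX/XY respectively.
    """
    base = GenomeModel.display_name(chrom)
    if base == "X":
        return 2.0 if sex == "XX" else 1.0
    if base == "Y":
        return 0.0 if sex == "XX" else 1.0
    return 2.0


def infer_sex(profile: BinProfile, genome: GenomeModel) -> str:
    """Infer XX/XY from median X and Y copy-number ratios.

    XX requires X near 2 and Y near 0, XY requires both near 1; the
    cutpoints sit at the midpoints (1.5 for X, 0.5 for Y) with the exact
    boundary excluded. Genomes without sex chromosomes give undetermined.
    """
    x_name = genome.sex_chrom_name("X")
    y_name = genome.sex_chrom_name("Y")
    if x_name is None or y_name is None or profile.cn_ratio is None:
        return "undetermined"
    x_med = float(np.median(profile.cn_ratio[genome.chrom_slice(x_name)]))
    y_med = float(np.median(profile.cn_ratio[genome.chrom_slice(y_name)]))
    if x_med > 1.5 and y_med < 0.5:
        return "XX"
    if x_med < 1.5 and y_med > 0.5:
        return "XY"
    return "undetermined"


def call_cnvs(
    segments: dict[str, list[Segment]],
    thresholds: tuple[float, float],
    genome: GenomeModel,
    min_cnv_length: int = 1_000_000,
    whole_chrom_fraction: float = 0.9,
    sex: str = "undetermined",
    annotate: bool = True,
) -> list[CnvCall]:
    """Convert threshold-passing segments into integer CNV calls.

    A segment is a gain/loss when its mean deviates from the chromosome's
    expected baseline by at least the dynamic threshold offset. On sex
    chromosomes the baseline follows the inferred sex (a Y at copy 2 in an
    XY embryo is a gain); with undetermined sex the sex chromosomes are
    not called. Adjacent same-direction passing segments are merged, the
    copy number is the rounded bin-weighted mean clamped to [0, 4], calls
    whose rounded copy number equals the baseline or whose length is below
    *min_cnv_length* are dropped.
    """
    gain_cut, loss_cut = thresholds
    gain_off = gain_cut - 2.0
    loss_off = 2.0 - loss_cut
    calls: list[CnvCall] = []
    for chrom, segs in segments.items():
        base = expected_cn(chrom, sex)
        is_sex = GenomeModel.display_name(chrom) in ("X", "Y")
        if is_sex and sex == "undetermined":
            continue
        # direction per segment relative to baseline
        runs: list[list[Segment]] = []
        directions: list[int] = []
        for seg in segs:
            dev = seg.mean_cn - base
            if dev >= gain_off:
                d = 1
            elif dev <= -loss_off:
                d = -1
            else:
                d = 0
            if d == 0:
                continue
            if runs and directions[-1] == d and runs[-1][-1].end_bin == seg.start_bin:
                runs[-1].append(seg)
            else:
                runs.append([seg])
                directions.append(d)
        chrom_length = genome.lengths[chrom]
        for run in runs:
            start_bp = run[0].start_bp
            end_bp = run[-1].end_bp
            n_bins = sum(s.n_bins for s in run)
            mean = sum(s.mean_cn * s.n_bins for s in run) / n_bins
            cn = int(np.clip(np.round(mean), 0, 4))
            if cn == int(round(base)):
                continue
            if end_bp - start_bp < min_cnv_length:
                continue
            scope = (
                "whole-chromosome"
                if end_bp - start_bp >= whole_chrom_fraction * chrom_length
                else "segmental"
            )
            band_s = band_e = None
            if annotate and genome.cytobands is not None:
                band_s = genome.band_at(chrom, start_bp)
                band_e = genome.band_at(chrom, end_bp - 1)
            calls.append(
                CnvCall(
                    chrom=chrom,
                    start_bp=start_bp,
                    end_bp=end_bp,
                    copy_number=cn,
                    scope=scope,
                    mean_cn=mean,
                    band_start=band_s,
                    band_end=band_e,
                )
            )
    return calls


def classify(calls: list[CnvCall]) -> str:
    """Four-way embryo classification from its CNV calls."""
    has_whole = any(c.scope == "whole-chromosome" for c in calls)
    has_seg = any(c.scope == "segmental" for c in calls)
    if has_whole and has_seg:
        return CLASS_BOTH
    if has_whole:
        return CLASS_NUMERICAL
    if has_seg:
        return CLASS_IMBALANCED
    return CLASS_EUPLOID


def format_call(call: CnvCall, genome: GenomeModel) -> str:
    """Render a call in 'seq' nomenclature with cytoband endpoints.

    Output coordinates are 1-based inclusive; the band at the start renders
    as ``pter`` when it is the chromosome's first band and the call starts
    in bin 0, and the band at the end renders as ``qter`` when it is the
    chromosome's terminal band.
    """
    bands = genome.chrom_bands(call.chrom)
    if call.start_bp < bands.iloc[0]["start"] or call.end_bp > bands.iloc[-1]["end"]:
        raise AnnotationError(
            f"call {call.chrom}:{call.start_bp}-{call.end_bp} outside cytoband coverage"
        )
    band_s = genome.band_at(call.chrom, call.start_bp)
    band_e = genome.band_at(call.chrom, call.end_bp - 1)
    first_band = str(bands.iloc[0]["band"])
    last_band = str(bands.iloc[-1]["band"])
    label_s = (
        "pter"
        if band_s == first_band and call.start_bp < genome.bin_size
        else band_s
    )
    label_e = "qter" if band_e == last_band else band_e
    disp = GenomeModel.display_name(call.chrom)
    start_1 = call.start_bp + 1
    end_1 = call.end_bp
    return f"seq {disp}{label_s} → {label_e}({start_1}–{end_1})×{call.copy_number}"


_CALL_RE = re.compile(
    r"^seq (?P<chrom>[0-9XY]+)(?P<bs>pter|[pq][\d.]+) → "
    r"(?P<be>qter|[pq][\d.]+)\((?P<start>\d+)–(?P<end>\d+)\)×(?P<cn>\d+)$"
)


def parse_call(text: str) -> dict:
    """Parse a 'seq' nomenclature string back to its components.

    Coordinates are returned in the internal 0-based half-open convention,
    so ``parse_call(format_call(c))`` round-trips chrom, coordinates and
    copy number exactly.
    """
    m = _CALL_RE.match(text)
    if m is None:
        raise ValueError(f"unparseable call string: {text!r}")
    return {
        "chrom": m["chrom"],
        "band_start": m["bs"],
        "band_end": m["be"],
        "start_bp": int(m["start"]) - 1,
        "end_bp": int(m["end"]),
        "copy_number": int(m["cn"]),
    }
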