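"""Genome model: the shared coordinate frame of the pipeline.

A :class:`GenomeModel` carries an ordered set of chromosomes, a fixed bin
grid (half-open ``[k*bin_size, (k+1)*bin_size)`` in 0-based coordinates,
last bin truncated at the chromosome end), a per-bin GC fraction track, an
optional cytoband map, and a mitochondrial contig that is kept off the bin
grid and analysed by depth only.

Sex chromosomes are recognised by name (``chrX``/``X``, ``chrY``/``Y``) and
are excluded from all autosomal statistics (normalisation median, MAD, GC
trend fitting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AnnotationError, InvalidSpecError

_SEX_NAMES = {"X", "Y", "chrX", "chrY"}


def _is_sex_name(name: str) -> bool:
    return name in _SEX_NAMES


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths, bin grid, GC track, cytobands and mito contig.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs for the nuclear genome. The
        mitochondrial contig is *not* listed here.
    bin_size
        Width of the binning grid in bp.
    gc_per_bin
        GC fraction per bin, concatenated in chromosome order.
    cytobands
        Optional DataFrame with columns ``chrom, start, end, band`` tiling
        each chromosome (0-based half-open).
    mito_name, mito_length
        Name and length of the mitochondrial contig.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    gc_per_bin: np.ndarray
    cytobands: pd.DataFrame | None = None
    mito_name: str = "chrM"
    mito_length: int = 16569

    # derived, filled in __post_init__
    _offsets: Mapping[str, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise InvalidSpecError("bin_size must be positive")
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvalidSpecError("duplicate chromosome names")
        gc = np.asarray(self.gc_per_bin, dtype=float)
        object.__setattr__(self, "gc_per_bin", gc)
        offsets, total = {}, 0
        for name, length in self.chromosomes:
            offsets[name] = total
            total += self._nbins(length)
        object.__setattr__(self, "_offsets", offsets)
        if gc.shape != (total,):
            raise InvalidSpecError(
                f"gc_per_bin has length {gc.size}, genome has {total} bins"
            )
        if gc.size and (gc.min() < 0.0 or gc.max() > 1.0):
            raise InvalidSpecError("gc_per_bin values must lie in [0, 1]")
        if self.cytobands is not None:
            _check_band_tiling(self.cytobands, dict(self.chromosomes))

    def _nbins(self, length: int) -> int:
        return -(-length // self.bin_size)

    # ------------------------------------------------------------------ bins
    @property
    def n_bins(self) -> int:
        return int(self.gc_per_bin.size)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def nuclear_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def chrom_slice(self, name: str) -> slice:
        """Bin-index slice of chromosome *name* in the concatenated track."""
        start = self._offsets[name]
        return slice(start, start + self._nbins(self.lengths[name]))

    def bin_chrom_index(self) -> np.ndarray:
        """Integer chromosome index per bin (order of ``chromosomes``)."""
        reps = [self._nbins(l) for _, l in self.chromosomes]
        return np.repeat(np.arange(len(reps)), reps)

    def bin_table(self) -> pd.DataFrame:
        """Per-bin ``chrom, start, end`` DataFrame in genome order."""
        rows = []
        for name, length in self.chromosomes:
            starts = np.arange(self._nbins(length)) * self.bin_size
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def autosomal_mask(self) -> np.ndarray:
        """Boolean mask over bins: True for autosomal bins."""
        mask = np.ones(self.n_bins, dtype=bool)
        for name, _ in self.chromosomes:
            if _is_sex_name(name):
                mask[self.chrom_slice(name)] = False
        return mask

    def has_sex_chromosomes(self) -> bool:
        return any(_is_sex_name(n) for n, _ in self.chromosomes)

    def sex_chrom_name(self, which: str) -> str | None:
        """Return the genome's name for 'X' or 'Y', or None if absent."""
        for cand in (which, "chr" + which):
            if cand in self._offsets:
                return cand
        return None

    @staticmethod
    def display_name(chrom: str) -> str:
        """Chromosome name as printed in karyotype strings ('chr2' -> '2')."""
        return chrom[3:] if chrom.startswith("chr") else chrom

    # ------------------------------------------------------------- cytobands
    def band_at(self, chrom: str, pos: int) -> str:
        """Cytoband label containing 0-based position *pos* on *chrom*."""
        if self.cytobands is None:
            raise AnnotationError("genome model has no cytoband map")
        sub = self.cytobands[self.cytobands["chrom"] == chrom]
        hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
        if hit.empty:
            raise AnnotationError(f"no cytoband covers {chrom}:{pos}")
        return str(hit.iloc[0]["band"])

    def chrom_bands(self, chrom: str) -> pd.DataFrame:
        if self.cytobands is None:
            raise AnnotationError("genome model has no cytoband map")
        sub = self.cytobands[self.cytobands["chrom"] == chrom]
        if sub.empty:
            raise AnnotationError(f"no cytobands for {chrom}")
        return sub.sort_values("start").reset_index(drop=True)

    # ------------------------------------------------------------------- IO
    def to_dict(self) -> dict:
        d = {
            "chromosomes": [[n, int(l)] for n, l in self.chromosomes],
            "bin_size": int(self.bin_size),
            "gc_per_bin": [round(float(g), 6) for g in self.gc_per_bin],
            "mito_name": self.mito_name,
            "mito_length": int(self.mito_length),
        }
        if self.cytobands is not None:
            d["cytobands"] = self.cytobands[["chrom", "start", "end", "band"]].to_dict(
                "records"
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeModel":
        bands = None
        if "cytobands" in d:
            bands = pd.DataFrame(d["cytobands"])
        return cls(
            chromosomes=tuple((str(n), int(l)) for n, l in d["chromosomes"]),
            bin_size=int(d["bin_size"]),
            gc_per_bin=np.asarray(d["gc_per_bin"], dtype=float),
            cytobands=bands,
            mito_name=str(d.get("mito_name", "chrM")),
            mito_length=int(d.get("mito_length", 16569)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "GenomeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_band_tiling(bands: pd.DataFrame, lengths: Mapping[str, int]) -> None:
    """Bands must tile each covered chromosome exactly: no gaps, no overlaps."""
    for chrom, sub in bands.groupby("chrom"):
        if chrom not in lengths:
            raise InvalidSpecError(f"cytoband chromosome {chrom!r} not in genome")
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if starts[0] != 0 or ends[-1] != lengths[chrom]:
            raise InvalidSpecError(f"cytobands do not span {chrom} end to end")
        if not np.all(starts[1:] == ends[:-1]):
            raise InvalidSpecError(f"cytobands on {chrom} have gaps or overlaps")
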