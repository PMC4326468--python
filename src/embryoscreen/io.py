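"""Readers and writers for the pipeline's plain-text interchange formats.

Read positions travel as 3-column BED-like TSV (chrom, start, end;
0-based half-open) or as SAM (positions taken from the alignment field,
converted from 1-based; flags/CIGAR are not interpreted beyond the unmapped
bit). Cytobands are read in the UCSC ``cytoBand.txt`` dialect
(chrom, start, end, band, stain — stain ignored). Genome models are JSON.
"""

from __future__ import annotations

import pandas as pd
import pysam

from .exceptions import InputMismatchError
from .genome import GenomeModel

__all__ = [
    "read_bed_reads",
    "write_bed_reads",
    "read_sam_reads",
    "read_reads",
    "read_cytoband",
    "read_genome_json",
    "write_genome_json",
]


def read_bed_reads(path) -> pd.DataFrame:
    """Read a 3-column BED-like file of read start positions.

    Returns a DataFrame with columns ``chrom`` (str) and ``start`` (int);
    the third column (end) is tolerated but not required.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1],
            names=["chrom", "start"],
            dtype={"chrom": str},
        )
        df["start"] = pd.to_numeric(df["start"], errors="raise").astype("int64")
    except (ValueError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputMismatchError(f"malformed reads file {path}: {exc}") from exc
    return df


def write_bed_reads(reads: pd.DataFrame, path, read_length: int = 50) -> None:
    """Write read positions as chrom / start / start+read_length TSV."""
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"],
            "end": reads["start"] + read_length,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sam_reads(path) -> pd.DataFrame:
    """Read mapped read start positions from a SAM file (0-based output)."""
    chroms, starts = [], []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)  # pysam is already 0-based
    return pd.DataFrame({"chrom": pd.Series(chroms, dtype=str),
                         "start": pd.Series(starts, dtype="int64")})


def read_reads(path) -> pd.DataFrame:
    """Dispatch on extension: ``.sam`` via pysam, anything else as BED."""
    if str(path).endswith(".sam"):
        return read_sam_reads(path)
    return read_bed_reads(path)


def read_cytoband(path) -> pd.DataFrame:
    """Parse a UCSC cytoBand.txt-style file into chrom/start/end/band."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str},
    )
    df["start"] = df["start"].astype("int64")
    df["end"] = df["end"].astype("int64")
    return df[["chrom", "start", "end", "band"]]


def read_genome_json(path) -> GenomeModel:
    return GenomeModel.from_json(path)


def write_genome_json(genome: GenomeModel, path) -> None:
    genome.to_json(path)
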