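"""Readers and writers for the external file formats.

BED6 / narrowPeak, FASTA, 4-column bedGraph and TSV differential-expression
tables are parsed into the internal data model with strict validation.  All
readers are gzip-transparent (a ``.gz`` suffix switches to gzip decoding).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import GenomicInterval, PeakSet

PathLike = Union[str, Path]

DE_TABLE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "log2fc", "pvalue", "fdr"]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class Genome:
    """Chromosome sequences over the A/C/G/T/N alphabet, uppercased on load."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = self.sequences[chrom]
        return seq[max(0, start):min(len(seq), end)]


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

def read_bed(path: PathLike, format_hint: str = "auto", label: Optional[str] = None) -> PeakSet:
    """Read BED3/BED6/narrowPeak into a sorted :class:`PeakSet`.

    Missing name/score/strand default to ``"."`` / 0 / ``"."``.  A
    narrowPeak column 10 >= 0 populates ``summit_offset``; -1 leaves it
    absent.  Track/browser lines are skipped.  Malformed lines raise
    :class:`FormatError` naming the line number.
    """
    if format_hint not in ("auto", "bed6", "narrowpeak"):
        raise ValueError(f"unknown format_hint {format_hint!r}")
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            if format_hint == "narrowpeak" and len(fields) != 10:
                raise FormatError(f"{path}:{lineno}: narrowPeak requires 10 fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "" else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] not in ("", ".") else 0.0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            summit = None
            if len(fields) == 10 and format_hint in ("auto", "narrowpeak"):
                try:
                    summit_raw = int(fields[9])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-integer summit column") from exc
                if summit_raw >= 0:
                    if summit_raw >= end - start:
                        raise FormatError(
                            f"{path}:{lineno}: summit offset {summit_raw} outside interval"
                        )
                    summit = summit_raw
            intervals.append(
                GenomicInterval(fields[0], start, end, name, score, strand, summit)
            )
    if not intervals:
        warnings.warn(f"{path}: empty peak file", stacklevel=2)
    return PeakSet(label or Path(path).stem, intervals)


def write_bed(
    peaks: PeakSet,
    path: PathLike,
    extra_columns: Optional[pd.DataFrame] = None,
    narrowpeak: bool = False,
) -> None:
    """Write BED6 (optionally +extra columns, or 10-column narrowPeak).

    The six standard fields round-trip losslessly through :func:`read_bed`.
    ``extra_columns`` rows must align with peak order.
    """
    if extra_columns is not None and len(extra_columns) != len(peaks):
        raise ValueError("extra_columns length must match peak count")
    with _open_text(path, "wt") as fh:
        for i, iv in enumerate(peaks):
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name,
                      f"{iv.score:g}", iv.strand]
            if narrowpeak:
                summit = iv.summit_offset if iv.summit_offset is not None else -1
                fields += ["0", "-1", "-1", str(summit)]
            elif extra_columns is not None:
                fields += [str(v) for v in extra_columns.iloc[i]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> Genome:
    """Load a FASTA file, uppercasing and mapping non-ACGTN characters to N.

    Duplicate headers (up to the first whitespace) are a hard error; the
    number of substituted characters is reported in a single warning.
    """
    sequences: dict[str, str] = {}
    n_subst = 0
    allowed = set(b"ACGTN")
    # uppercase first, then map anything outside ACGTN to N
    upper = bytes(range(256)).upper()
    trans = bytes((b if b in allowed else ord("N")) for b in upper)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in sequences:
                raise FormatError(f"{path}: duplicate FASTA header {rec.id!r}")
            raw = bytes(str(rec.seq), "ascii")
            clean = raw.translate(trans)
            upper_only = raw.upper()
            n_subst += sum(1 for a, b in zip(upper_only, clean) if a != b)
            sequences[rec.id] = clean.decode("ascii")
    if n_subst:
        warnings.warn(f"{path}: replaced {n_subst} non-ACGTN characters with N", stacklevel=2)
    return Genome(sequences)


def write_fasta(genome: Genome, path: PathLike, line_width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: PathLike, genome_lengths: dict[str, int], label: Optional[str] = None):
    """Load a 4-column bedGraph into a dense per-base CoverageTrack.

    Uncovered bases are 0.  Overlapping input intervals are rejected: the
    signal there would be ambiguous and silently summing corrupts window
    means.  Intervals beyond the declared chromosome length, or on unknown
    chromosomes, are hard errors.
    """
    from .signal import CoverageTrack

    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    df = df[~df["chrom"].str.startswith(("track", "browser", "#"))]
    try:
        df = df.astype({"start": np.int64, "end": np.int64, "value": np.float64})
    except ValueError as exc:
        raise FormatError(f"{path}: malformed bedGraph fields") from exc
    data = {c: np.zeros(length, dtype=np.float32) for c, length in genome_lengths.items()}
    if not np.isfinite(df["value"]).all():
        raise FormatError(f"{path}: non-finite signal value")
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in genome_lengths:
            raise FormatError(f"{path}: unknown chromosome {chrom!r}")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (ends <= starts).any() or (starts < 0).any():
            raise FormatError(f"{path}: invalid interval on {chrom}")
        if ends.max() > genome_lengths[chrom]:
            raise FormatError(
                f"{path}: interval beyond length of {chrom} ({genome_lengths[chrom]} bp)"
            )
        order = np.argsort(starts, kind="stable")
        if (ends[order][:-1] > starts[order][1:]).any():
            raise FormatError(f"{path}: overlapping bedGraph intervals on {chrom}")
        arr = data[chrom]
        for s, e, v in zip(starts, ends, grp["value"].to_numpy()):
            arr[s:e] = v
    return CoverageTrack(label or Path(path).stem, data)


def write_bedgraph(track, path: PathLike) -> None:
    """Write a CoverageTrack as run-length-encoded bedGraph (zeros skipped)."""
    frames = []
    for chrom in sorted(track.data):
        arr = np.asarray(track.data[chrom], dtype=np.float64)
        if arr.size == 0:
            continue
        change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        values = arr[starts]
        keep = values != 0.0
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts[keep], "end": ends[keep],
                          "value": values[keep]})
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "value"]
    )
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

def read_de_table(path: PathLike) -> pd.DataFrame:
    """Read a TSV differential-expression table.

    Requires columns ``gene_id, chrom, tss, strand, log2fc, pvalue, fdr``
    (``tss`` is a 0-based genomic coordinate).  Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in ("tss", "log2fc", "pvalue", "fdr"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise FormatError(f"{path}: non-numeric {col!r} at data row {row + 1}")
        df[col] = numeric
    df["fold_change"] = 2.0 ** df["log2fc"].abs()
    return df


def write_de_table(df: pd.DataFrame, path: PathLike) -> None:
    df.loc[:, DE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)
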