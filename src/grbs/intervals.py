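"""Genomic intervals and sorted peak sets.

Coordinates are BED-native throughout: 0-based, half-open ``[start, end)``.
The length of an interval is ``end - start`` and two intervals overlap iff
they share at least one base, i.e. ``a.start < b.end and b.start < a.end``
on the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span with optional name/score/strand/summit.

    ``summit_offset`` is the narrowPeak column-10 convention: an offset from
    ``start`` pointing at the highest-signal base, or ``None`` when absent.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    summit_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a nonempty string")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside interval of width "
                f"{self.end - self.start}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def anchor(self) -> int:
        """Summit position when known, otherwise the interval midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return self.midpoint

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


class PeakSet:
    """An immutable, sorted collection of :class:`GenomicInterval`.

    Intervals are kept sorted by ``(chrom, start, end)``; per-chromosome
    coordinate arrays are cached for the sweep/bisection queries in
    :mod:`grbs.engine`.
    """

    def __init__(self, label: str, intervals: Iterable[GenomicInterval]):
        self.label = label
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=GenomicInterval.sort_key)
        )
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        self._build_index()

    def _build_index(self) -> None:
        chroms: dict[str, list[int]] = {}
        for i, iv in enumerate(self.intervals):
            chroms.setdefault(iv.chrom, []).append(i)
        for chrom, idx in chroms.items():
            idx_arr = np.asarray(idx, dtype=np.intp)
            starts = np.asarray([self.intervals[i].start for i in idx], dtype=np.int64)
            ends = np.asarray([self.intervals[i].end for i in idx], dtype=np.int64)
            anchors = np.asarray([self.intervals[i].anchor for i in idx], dtype=np.int64)
            order = np.argsort(anchors, kind="stable")
            self._by_chrom[chrom] = {
                "index": idx_arr,
                "starts": starts,              # sorted (set order is by start)
                "ends": ends,                  # aligned with starts
                "ends_sorted": np.sort(ends),
                "anchors_sorted": anchors[order],
                "anchors_index": idx_arr[order],
            }

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.label == other.label and self.intervals == other.intervals

    # -- indexed access -----------------------------------------------------
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def chrom_data(self, chrom: str) -> Optional[dict[str, np.ndarray]]:
        return self._by_chrom.get(chrom)

    def subset(self, indices: Sequence[int], label: Optional[str] = None) -> "PeakSet":
        return PeakSet(label or self.label, (self.intervals[i] for i in indices))

    def replace_label(self, label: str) -> "PeakSet":
        ps = PeakSet.__new__(PeakSet)
        ps.label = label
        ps.intervals = self.intervals
        ps._by_chrom = self._by_chrom
        return ps


class TSSSet(PeakSet):
    """A PeakSet whose records are 1-bp transcription start sites."""

    def __init__(self, label: str, intervals: Iterable[GenomicInterval]):
        intervals = tuple(intervals)
        for iv in intervals:
            if iv.end != iv.start + 1:
                raise ValueError(
                    f"TSS records must be 1 bp wide, got [{iv.start}, {iv.end}) on {iv.chrom}"
                )
        super().__init__(label, intervals)

    def positions(self, chrom: str) -> np.ndarray:
        data = self.chrom_data(chrom)
        if data is None:
            return np.empty(0, dtype=np.int64)
        return data["starts"]
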