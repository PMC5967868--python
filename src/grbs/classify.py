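"""Three-class partition of GR peaks by BRG1 co-occupancy.

A GR peak is Class I when no BRG1 peak touches it in either condition,
Class II when BRG1 peaks overlap it both before (vehicle/EtOH) and after
(Dex) hormone, and Class III when only the post-hormone BRG1 set overlaps
it.  The small residual of peaks overlapped only by vehicle-condition BRG1
is kept explicitly as "other" rather than silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import any_overlap
from .intervals import GenomicInterval, PeakSet

CLASS_LABELS = ("I", "II", "III", "other")


@dataclass(frozen=True)
class ClassifiedPeak:
    interval: GenomicInterval
    overlaps_etoh: bool
    overlaps_dex: bool
    gr_class: str

    def __post_init__(self) -> None:
        expected = _label(self.overlaps_etoh, self.overlaps_dex)
        if self.gr_class != expected:
            raise ValueError(
                f"label {self.gr_class!r} inconsistent with flags "
                f"(etoh={self.overlaps_etoh}, dex={self.overlaps_dex})"
            )


def _label(etoh: bool, dex: bool) -> str:
    if etoh and dex:
        return "II"
    if dex:
        return "III"
    if etoh:
        return "other"
    return "I"


def classify_gr_peaks(
    gr: PeakSet, brg1_etoh: PeakSet, brg1_dex: PeakSet
) -> list[ClassifiedPeak]:
    """Label every GR peak I/II/III/other from per-condition overlap flags.

    Overlap is >= 1 shared bp against each full condition peak set;
    "Dex-specific BRG1" is derived at the GR-peak level as
    (overlaps Dex set) and not (overlaps EtOH set).  Output order follows
    the (sorted) GR set.
    """
    if len(gr) == 0:
        raise ValueError("empty GR peak set")
    flags_etoh = any_overlap(gr, brg1_etoh)
    flags_dex = any_overlap(gr, brg1_dex)
    return [
        ClassifiedPeak(iv, bool(e), bool(d), _label(bool(e), bool(d)))
        for iv, e, d in zip(gr, flags_etoh, flags_dex)
    ]


@dataclass
class ClassSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    width_quantiles: dict[str, dict[str, float]]   # class -> {q25, median, q75}

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "fractions": self.fractions,
             "width_quantiles": self.width_quantiles},
            indent=2,
        )


def summarize_classes(classified: Sequence[ClassifiedPeak]) -> ClassSummary:
    """Counts, fractions and width quartiles per class (width = end - start)."""
    if not classified:
        raise ValueError("nothing to summarize")
    counts = {c: 0 for c in CLASS_LABELS}
    widths: dict[str, list[int]] = {c: [] for c in CLASS_LABELS}
    for cp in classified:
        counts[cp.gr_class] += 1
        widths[cp.gr_class].append(cp.interval.width)
    n = len(classified)
    fractions = {c: counts[c] / n for c in CLASS_LABELS}
    quantiles = {}
    for c in CLASS_LABELS:
        if widths[c]:
            q25, q50, q75 = np.percentile(widths[c], [25, 50, 75])
            quantiles[c] = {"q25": float(q25), "median": float(q50), "q75": float(q75)}
    return ClassSummary(counts, fractions, quantiles)


def class_subsets(
    classified: Sequence[ClassifiedPeak], include_other: bool = False
) -> dict[str, PeakSet]:
    """Per-class PeakSets (Classes I/II/III; 'other' only on request)."""
    wanted = CLASS_LABELS if include_other else CLASS_LABELS[:3]
    out = {}
    for c in wanted:
        ivs = [cp.interval for cp in classified if cp.gr_class == c]
        if ivs:
            out[c] = PeakSet(f"GR_class_{c}", ivs)
    return out


def split_by_overlap(pioneer: PeakSet, brg1: PeakSet) -> tuple[PeakSet, PeakSet]:
    """Partition a (pioneer-factor) peak set by BRG1 overlap.

    Returns ``(with_brg1, without_brg1)``; the two parts are disjoint and
    jointly exhaust the input.
    """
    flags = any_overlap(pioneer, brg1)
    with_idx = np.flatnonzero(flags)
    without_idx = np.flatnonzero(~flags)
    return (
        pioneer.subset(with_idx, f"{pioneer.label}_with_{brg1.label}"),
        pioneer.subset(without_idx, f"{pioneer.label}_without_{brg1.label}"),
    )


_FLAGS_FROM_LABEL = {"I": (False, False), "II": (True, True),
                     "III": (False, True), "other": (True, False)}


def write_classified_bed(
    classified: Sequence[ClassifiedPeak], path, header_lines: Iterable[str] = ()
) -> None:
    """BED6 + class label (column 7), with optional '#' header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for cp in classified:
            iv = cp.interval
            fh.write(
                "\t".join([iv.chrom, str(iv.start), str(iv.end), iv.name,
                           f"{iv.score:g}", iv.strand, cp.gr_class]) + "\n"
            )


def read_classified_bed(path) -> list[ClassifiedPeak]:
    """Re-load a classified BED; overlap flags are implied by the label."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7 or fields[6] not in _FLAGS_FROM_LABEL:
                raise ValueError(f"{path}:{lineno}: expected BED6 + class column")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]),
                                 fields[3], float(fields[4]), fields[5])
            etoh, dex = _FLAGS_FROM_LABEL[fields[6]]
            out.append(ClassifiedPeak(iv, etoh, dex, fields[6]))
    return out


def classified_table(classified: Sequence[ClassifiedPeak]) -> pd.DataFrame:
    """BED6+class export frame (column 7 = gr_class)."""
    rows = [
        (cp.interval.chrom, cp.interval.start, cp.interval.end, cp.interval.name,
         cp.interval.score, cp.interval.strand, cp.gr_class)
        for cp in classified
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand", "gr_class"]
    )
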