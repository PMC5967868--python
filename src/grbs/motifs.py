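"""Mismatch scanning for the GRE consensus under peaks.

The default model is the canonical inverted-repeat glucocorticoid response
element AGAACAnnnTGTTCT: two 6-bp half-sites on opposite strands separated
by a fully degenerate 3-bp spacer.  The 12 non-spacer positions are
"informative"; a window's mismatch count is the number of informative
positions whose base differs from the consensus (an N in the genome always
counts as a mismatch, the spacer never does).  The default consensus is its
own reverse complement, so a forward-strand scan finds every occurrence
exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import CLASS_LABELS, ClassifiedPeak
from .formats import Genome
from .intervals import PeakSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A consensus over {A,C,G,T,N}; N marks fully degenerate positions."""

    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus or set(self.consensus) - set("ACGTN"):
            raise ValueError("consensus must be a nonempty string over ACGTN")

    @property
    def length(self) -> int:
        return len(self.consensus)

    @property
    def informative_positions(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.consensus) if b != "N")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.consensus) == self.consensus


DEFAULT_GRE = MotifModel("AGAACANNNTGTTCT")


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    position: int        # 0-based start of the matched window
    strand: str
    mismatches: int


def _mismatch_counts(seq_arr: np.ndarray, consensus: str) -> np.ndarray:
    """Vector of mismatch counts for every window start (informative positions)."""
    n_win = seq_arr.size - len(consensus) + 1
    counts = np.zeros(n_win, dtype=np.int16)
    for j, base in enumerate(consensus):
        if base == "N":
            continue
        counts += seq_arr[j:j + n_win] != ord(base)
    return counts


def scan_sequence(
    seq: str,
    model: MotifModel = DEFAULT_GRE,
    max_mismatch: int = 0,
    chrom: str = ".",
    offset: int = 0,
) -> list[MotifHit]:
    """All windows matching the consensus with <= ``max_mismatch`` mismatches.

    Overlapping hits are all reported.  For a palindromic model only the
    forward strand is scanned (each genomic occurrence is a single hit,
    strand "+"); otherwise both the consensus and its reverse complement
    are matched against the forward sequence, the latter reported with
    strand "-".  ``offset`` shifts reported positions into genome
    coordinates when ``seq`` is a slice.
    """
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    if len(seq) < model.length:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits: list[MotifHit] = []
    strands = [("+", model.consensus)]
    if not model.is_palindromic:
        strands.append(("-", reverse_complement(model.consensus)))
    per_pos: dict[int, list[MotifHit]] = {}
    for strand, consensus in strands:
        counts = _mismatch_counts(arr, consensus)
        for pos in np.flatnonzero(counts <= max_mismatch):
            per_pos.setdefault(int(pos), []).append(
                MotifHit(chrom, int(pos) + offset, strand, int(counts[pos]))
            )
    for pos in sorted(per_pos):
        hits.extend(per_pos[pos])
    return hits


def best_hit_per_peak(
    peaks: PeakSet,
    genome: Genome,
    model: MotifModel = DEFAULT_GRE,
    max_mismatch: int = 1,
    window_mode: str = "under_peak",
    half_window_bp: int = 250,
) -> list[Optional[MotifHit]]:
    """Best (fewest-mismatch, then leftmost) hit per peak, or None.

    ``under_peak`` searches the full peak span; ``around_center`` searches
    ``[center - half_window_bp, center + half_window_bp)`` where the centre
    is the summit when present, else the midpoint.  Windows are clipped to
    chromosome bounds.
    """
    if window_mode not in ("under_peak", "around_center"):
        raise ValueError("window_mode must be 'under_peak' or 'around_center'")
    best: list[Optional[MotifHit]] = []
    for iv in peaks:
        if iv.chrom not in genome.sequences:
            raise KeyError(f"chromosome {iv.chrom!r} missing from genome")
        if window_mode == "under_peak":
            w0, w1 = iv.start, iv.end
        else:
            c = iv.anchor
            w0, w1 = c - half_window_bp, c + half_window_bp
        w0 = max(0, w0)
        w1 = min(len(genome.sequences[iv.chrom]), w1)
        hits = scan_sequence(
            genome.fetch(iv.chrom, w0, w1), model, max_mismatch, chrom=iv.chrom, offset=w0
        )
        best.append(min(hits, key=lambda h: (h.mismatches, h.position)) if hits else None)
    return best


def gre_fraction_report(
    classified: Sequence[ClassifiedPeak],
    genome: Genome,
    model: MotifModel = DEFAULT_GRE,
    window_mode: str = "under_peak",
    half_window_bp: int = 250,
) -> pd.DataFrame:
    """Per-class fractions of peaks with a perfect / 1-mismatch-only / no GRE.

    Rows: Classes I/II/III (and 'other' when populated) plus an 'all' row
    over every classified peak.  The three fractions sum to 1 per row.
    """
    by_class: dict[str, list[ClassifiedPeak]] = {c: [] for c in CLASS_LABELS}
    for cp in classified:
        by_class[cp.gr_class].append(cp)
    rows = []
    groups = [("all", list(classified))] + [(c, by_class[c]) for c in CLASS_LABELS]
    for name, group in groups:
        if not group:
            if name != "all":
                warnings.warn(f"class {name} empty; row omitted", stacklevel=2)
            continue
        ps = PeakSet(f"class_{name}", [cp.interval for cp in group])
        hits = best_hit_per_peak(ps, genome, model, max_mismatch=1,
                                 window_mode=window_mode, half_window_bp=half_window_bp)
        n = len(hits)
        n_perfect = sum(1 for h in hits if h is not None and h.mismatches == 0)
        n_1mm = sum(1 for h in hits if h is not None and h.mismatches == 1)
        rows.append(
            {"gr_class": name, "n": n,
             "frac_perfect": n_perfect / n,
             "frac_1mm": n_1mm / n,
             "frac_none": (n - n_perfect - n_1mm) / n}
        )
    return pd.DataFrame(rows)
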