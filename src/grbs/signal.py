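"""Coverage aggregation over peaks and the unpaired rank-sum test.

Heatmap matrices and meta-profiles follow the usual anchored-window scheme:
each peak contributes a row of per-bin mean signal over a window of
``2 * window_half_bp`` centred on its summit (when known) or midpoint.
Windows clipped at chromosome ends average only the in-bounds bases, so
boundary rows are unbiased rather than zero-padded.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet


@dataclass
class CoverageTrack:
    """Dense per-base real-valued signal for a set of chromosomes."""

    label: str
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=np.float32)
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite signal on {chrom}")
            self.data[chrom] = arr

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def chrom_values(self, chrom: str) -> np.ndarray:
        if chrom not in self.data:
            raise KeyError(f"chromosome {chrom!r} not in track {self.label!r}")
        return self.data[chrom]

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(self.label, {c: a * factor for c, a in self.data.items()})


@dataclass
class SignalMatrix:
    """Peaks x bins aggregation of one track (heatmap / meta-profile input)."""

    row_ids: list[str]
    values: np.ndarray            # rows x bins
    bin_width_bp: int
    window_half_bp: int
    anchor: str

    @property
    def bins(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided unpaired Wilcoxon rank-sum / Mann-Whitney result."""

    n1: int
    n2: int
    statistic: float              # Mann-Whitney U for the first sample
    p_value: float
    method: str                   # normal_approx_tie_corrected | exact_permutation


def _anchor_positions(peaks: PeakSet, anchor: str) -> np.ndarray:
    if anchor not in ("center", "summit"):
        raise ValueError("anchor must be 'center' or 'summit'")
    if anchor == "center":
        return np.asarray([iv.midpoint for iv in peaks], dtype=np.int64)
    return np.asarray([iv.anchor for iv in peaks], dtype=np.int64)


def build_matrix(
    track: CoverageTrack,
    peaks: PeakSet,
    window_half_bp: int = 2000,
    bin_width_bp: int = 25,
    anchor: str = "summit",
) -> SignalMatrix:
    """Per-peak binned mean signal over anchored windows, in peak order."""
    if window_half_bp % bin_width_bp != 0:
        raise ValueError("window_half_bp must be divisible by bin_width_bp")
    n_bins = 2 * window_half_bp // bin_width_bp
    centers = _anchor_positions(peaks, anchor)
    values = np.zeros((len(peaks), n_bins), dtype=np.float64)
    for i, (iv, c) in enumerate(zip(peaks, centers)):
        arr = track.chrom_values(iv.chrom)
        w0 = int(c) - window_half_bp
        w1 = int(c) + window_half_bp
        if w0 >= 0 and w1 <= len(arr):
            values[i] = arr[w0:w1].reshape(n_bins, bin_width_bp).mean(axis=1)
        else:
            for b in range(n_bins):
                b0 = max(0, w0 + b * bin_width_bp)
                b1 = min(len(arr), w0 + (b + 1) * bin_width_bp)
                if b1 > b0:
                    values[i, b] = arr[b0:b1].mean()
    return SignalMatrix([iv.name for iv in peaks], values, bin_width_bp, window_half_bp, anchor)


def meta_profile(matrix: SignalMatrix, stat: str = "mean") -> np.ndarray:
    """Per-bin column mean (or median) across all rows."""
    if matrix.values.shape[0] == 0:
        raise ValueError("meta_profile of an empty matrix")
    if stat == "mean":
        return matrix.values.mean(axis=0)
    if stat == "median":
        return np.median(matrix.values, axis=0)
    raise ValueError("stat must be 'mean' or 'median'")


def window_means(track: CoverageTrack, peaks: PeakSet, window_bp: int = 500) -> pd.DataFrame:
    """Mean per-base signal in a fixed window centred on each peak's centre.

    The window is ``[center - w/2, center + w/2)``; windows clipped at
    chromosome ends average the in-bounds bases only.
    """
    if window_bp <= 0 or window_bp % 2 != 0:
        raise ValueError("window_bp must be even and > 0")
    half = window_bp // 2
    means = np.zeros(len(peaks))
    for i, iv in enumerate(peaks):
        arr = track.chrom_values(iv.chrom)
        c = iv.anchor
        w0, w1 = max(0, c - half), min(len(arr), c + half)
        means[i] = arr[w0:w1].mean() if w1 > w0 else 0.0
    return pd.DataFrame({"peak_id": [iv.name for iv in peaks], "mean_signal": means})


# ---------------------------------------------------------------------------
# Unpaired Wilcoxon rank-sum / Mann-Whitney test
# ---------------------------------------------------------------------------

EXACT_MAX_N = 20


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating all group assignments (handles ties).

    p = fraction of assignments whose U statistic is at least as far from
    the null mean n1*n2/2 as the observed one.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n = len(a), len(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * (n - n1) / 2
    dev_obs = abs(u_obs - center)
    count = total = 0
    offset = n1 * (n1 + 1) / 2
    for comb in itertools.combinations(range(n), n1):
        u = sum(ranks[i] for i in comb) - offset
        total += 1
        if abs(u - center) >= dev_obs - 1e-9:
            count += 1
    return float(u_obs), count / total


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney) test.

    Small samples (n1 + n2 <= 20) are handled by exact enumeration of all
    group assignments, which remains valid under ties; larger samples use
    the tie-corrected normal approximation with a 0.5 continuity
    correction.  Two degenerate groups of one identical value return p = 1
    with a warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be nonempty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")
    n1, n2 = int(a.size), int(b.size)
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        return RankSumResult(n1, n2, n1 * n2 / 2, 1.0, "degenerate_ties")
    if n1 + n2 <= EXACT_MAX_N:
        u, p = _exact_rank_sum_p(a, b)
        return RankSumResult(n1, n2, u, p, "exact_permutation")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return RankSumResult(n1, n2, float(res.statistic), float(min(res.pvalue, 1.0)),
                         "normal_approx_tie_corrected")
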