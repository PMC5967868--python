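"""Independent brute-force reference implementations used only by tests.

Each oracle is written as the literal definition of the quantity it checks
(all-pairs scans, exhaustive window enumeration, definitional step-up) and
shares no code with the package's optimized paths.
"""

from __future__ import annotations

import numpy as np


def brute_overlap_flags(query_ivs, subject_ivs) -> np.ndarray:
    """All-pairs existence of a >= 1 bp overlap, per query interval."""
    flags = np.zeros(len(query_ivs), dtype=bool)
    for i, q in enumerate(query_ivs):
        for s in subject_ivs:
            if q.chrom == s.chrom and s.start < q.end and q.start < s.end:
                flags[i] = True
                break
    return flags


def brute_point_to_interval(point: int, chrom: str, subject_ivs):
    """(distance, index) of the nearest subject interval, or (None, None)."""
    best = None
    best_i = None
    for i, s in enumerate(subject_ivs):
        if s.chrom != chrom:
            continue
        if s.start <= point < s.end:
            d = 0
        elif point < s.start:
            d = s.start - point
        else:
            d = point - (s.end - 1)
        if best is None or d < best or (d == best and s.start < subject_ivs[best_i].start):
            best, best_i = d, i
    return best, best_i


def brute_count_within(point: int, chrom: str, subject_ivs, radius: int) -> int:
    n = 0
    for s in subject_ivs:
        if s.chrom == chrom and abs(s.anchor - point) <= radius:
            n += 1
    return n


def brute_interval_to_point(iv, points) -> float:
    best = np.inf
    for p in points:
        if p.chrom != iv.chrom:
            continue
        pos = p.start
        if iv.start <= pos < iv.end:
            d = 0.0
        elif pos < iv.start:
            d = iv.start - pos
        else:
            d = pos - (iv.end - 1)
        best = min(best, d)
    return best


def brute_scan(seq: str, consensus: str, max_mismatch: int):
    """Every window position with its exact informative-position mismatch count."""
    L = len(consensus)
    out = []
    for pos in range(len(seq) - L + 1):
        mm = 0
        for a, b in zip(seq[pos:pos + L], consensus):
            if b != "N" and a != b:
                mm += 1
        if mm <= max_mismatch:
            out.append((pos, mm))
    return out


def bh_stepup(pvalues) -> np.ndarray:
    """Literal min-scan Benjamini-Hochberg step-up definition."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=500):
    """Random GenomicIntervals for property tests."""
    from grbs import GenomicInterval

    out = []
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, f"iv{i}"))
    return out


def random_points(rng, n, chroms=("chr1", "chr2"), max_pos=100_000):
    from grbs import GenomicInterval

    out = []
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        pos = int(rng.integers(0, max_pos))
        out.append(GenomicInterval(chrom, pos, pos + 1, f"p{i}"))
    return out
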