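"""Sorted-interval algebra: overlap, closest-feature and windowed queries.

All operations work on :class:`~grbs.intervals.PeakSet` objects and rely on
the per-chromosome sorted coordinate arrays the set caches, so each query is
a handful of binary searches rather than an all-pairs scan.  Results are
numpy arrays aligned with the query set's interval order.

Conventions
-----------
* overlap means >= 1 shared base under half-open coordinates;
* point-to-interval distance is 0 when the point lies inside the interval,
  otherwise the distance to the nearest covered base (``start`` or
  ``end - 1``);
* distances are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .intervals import PeakSet


class Direction(str, Enum):
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    OVERLAPPING = "overlapping"
    NONE = "none"


@dataclass(frozen=True)
class DistanceResult:
    """Nearest subject interval for one query point."""

    query_index: int
    nearest_index: Optional[int]
    distance_bp: int
    direction: Direction


def any_overlap(query: PeakSet, subject: PeakSet) -> np.ndarray:
    """Boolean per query interval: does it share >= 1 bp with any subject?

    Counting argument on sorted arrays: among subject intervals on the same
    chromosome, the number overlapping ``[qs, qe)`` equals
    ``#(start < qe) - #(end <= qs)``.
    """
    flags = np.zeros(len(query), dtype=bool)
    for chrom in query.chroms():
        qdata = query.chrom_data(chrom)
        sdata = subject.chrom_data(chrom)
        if sdata is None:
            continue
        n_start_lt = np.searchsorted(sdata["starts"], qdata["ends"], side="left")
        n_end_le = np.searchsorted(sdata["ends_sorted"], qdata["starts"], side="right")
        flags[qdata["index"]] = n_start_lt > n_end_le
    return flags


def _prefix_argmax_end(ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Running maximum of ends (in start order) and the argmax position."""
    run_max = np.maximum.accumulate(ends)
    # first position achieving each running max -> lowest start among ties
    is_new = np.empty(len(ends), dtype=bool)
    is_new[0] = True
    is_new[1:] = ends[1:] > run_max[:-1]
    arg = np.maximum.accumulate(np.where(is_new, np.arange(len(ends)), 0))
    return run_max, arg


def closest_distance(query_points: PeakSet, subject: PeakSet) -> list[DistanceResult]:
    """Per query anchor point, the nearest subject interval edge distance.

    Query records are treated as points at their ``start`` coordinate (TSS
    records are 1 bp wide).  Distance is 0 when the point lies inside a
    subject interval.  Ties between an upstream and a downstream candidate
    at equal distance resolve to the lower start coordinate (the upstream
    one).  A query chromosome absent from the subject yields no neighbour.
    """
    results: list[DistanceResult] = [None] * len(query_points)  # type: ignore[list-item]
    for chrom in query_points.chroms():
        qdata = query_points.chrom_data(chrom)
        sdata = subject.chrom_data(chrom)
        if sdata is None:
            for qi in qdata["index"]:
                results[qi] = DistanceResult(int(qi), None, 0, Direction.NONE)
            continue
        starts, ends, sidx = sdata["starts"], sdata["ends"], sdata["index"]
        run_max_end, run_arg = _prefix_argmax_end(ends)
        points = qdata["starts"]
        j = np.searchsorted(starts, points, side="right") - 1  # last start <= p
        for p, jj, qi in zip(points, j, qdata["index"]):
            left_dist = right_dist = None
            left_idx = right_idx = None
            if jj >= 0:
                max_end = run_max_end[jj]
                if max_end > p:  # contained
                    results[qi] = DistanceResult(
                        int(qi), int(sidx[run_arg[jj]]), 0, Direction.OVERLAPPING
                    )
                    continue
                left_dist = int(p - (max_end - 1))
                left_idx = int(sidx[run_arg[jj]])
            if jj + 1 < len(starts):
                right_dist = int(starts[jj + 1] - p)
                right_idx = int(sidx[jj + 1])
            if left_dist is None and right_dist is None:
                results[qi] = DistanceResult(int(qi), None, 0, Direction.NONE)
            elif right_dist is None or (left_dist is not None and left_dist <= right_dist):
                results[qi] = DistanceResult(int(qi), left_idx, left_dist, Direction.UPSTREAM)
            else:
                results[qi] = DistanceResult(int(qi), right_idx, right_dist, Direction.DOWNSTREAM)
    return results


def count_within(query_points: PeakSet, subject: PeakSet, radius_bp: int) -> np.ndarray:
    """Number of subject anchors within ``[point - r, point + r]`` per query.

    Subject intervals are anchored at their summit when present, else their
    midpoint, so a 50-kb window is counted against a single representative
    position per peak.
    """
    if radius_bp <= 0:
        raise ValueError("radius_bp must be > 0")
    counts = np.zeros(len(query_points), dtype=np.int64)
    for chrom in query_points.chroms():
        qdata = query_points.chrom_data(chrom)
        sdata = subject.chrom_data(chrom)
        if sdata is None:
            continue
        anchors = sdata["anchors_sorted"]
        points = qdata["starts"]
        hi = np.searchsorted(anchors, points + radius_bp, side="right")
        lo = np.searchsorted(anchors, points - radius_bp, side="left")
        counts[qdata["index"]] = hi - lo
    return counts


def interval_to_point_distance(query: PeakSet, points: PeakSet) -> np.ndarray:
    """Per query interval, distance to the nearest point (inf when none).

    Distance is 0 when some point lies inside ``[start, end)``, otherwise
    the gap between the nearest point and the closest covered base.
    """
    out = np.full(len(query), np.inf)
    for chrom in query.chroms():
        qdata = query.chrom_data(chrom)
        pdata = points.chrom_data(chrom)
        if pdata is None:
            continue
        pos = pdata["starts"]  # 1-bp records -> point = start
        starts, ends = qdata["starts"], qdata["ends"]
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        dist = np.full(len(starts), np.inf)
        inside = hi > lo
        dist[inside] = 0.0
        notin = ~inside
        left = lo[notin] - 1
        has_left = left >= 0
        left_d = np.full(notin.sum(), np.inf)
        left_d[has_left] = starts[notin][has_left] - pos[left[has_left]]
        right = lo[notin]
        has_right = right < len(pos)
        right_d = np.full(notin.sum(), np.inf)
        right_d[has_right] = pos[right[has_right]] - (ends[notin][has_right] - 1)
        dist[notin] = np.minimum(left_d, right_d)
        out[qdata["index"]] = dist
    return out


def fraction_within(query: PeakSet, points: PeakSet, threshold_bp: int) -> float:
    """Fraction of query intervals within ``threshold_bp`` of a point.

    Edge-to-point distance; a point inside the interval counts as 0.
    """
    if threshold_bp <= 0:
        raise ValueError("threshold_bp must be > 0")
    if len(query) == 0:
        raise ValueError("fraction undefined for an empty query set")
    if len(points) == 0:
        return 0.0
    dist = interval_to_point_distance(query, points)
    return float(np.mean(dist <= threshold_bp))


def set_partition(a: PeakSet, b: PeakSet) -> tuple[list[int], list[int], tuple[list[int], list[int]]]:
    """Split two peak sets by mutual overlap flags.

    Returns ``(a_only, b_only, (a_shared, b_shared))`` as index lists into
    each input.  This is a per-peak Venn on overlap flags: an ``a`` interval
    is shared iff it overlaps >= 1 ``b`` interval, and symmetrically, so the
    two shared counts need not agree.
    """
    fa = any_overlap(a, b)
    fb = any_overlap(b, a)
    a_only = [int(i) for i in np.flatnonzero(~fa)]
    b_only = [int(i) for i in np.flatnonzero(~fb)]
    shared = ([int(i) for i in np.flatnonzero(fa)], [int(i) for i in np.flatnonzero(fb)])
    return a_only, b_only, shared
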