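"""Peak-to-TSS proximity and DEG-to-peak linkage.

"Enhancer TSSs" are actively transcribed start sites more than a fixed
distance (default 2 kb, strict) from any annotated gene TSS.  Proximity of
a peak to a TSS is measured peak-edge to TSS-point (0 when the TSS lies
inside the peak); distances from a DEG TSS to its closest GR peak follow
the same convention and are unstranded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import CLASS_LABELS, ClassifiedPeak
from .engine import (
    closest_distance,
    count_within,
    interval_to_point_distance,
)
from .intervals import GenomicInterval, PeakSet, TSSSet
from .signal import rank_sum_test

DEG_CATEGORIES = ("common", "lost", "gained", "neither")


def split_enhancer_tss(
    all_tss: TSSSet, gene_tss: TSSSet, min_distance_bp: int = 2000
) -> tuple[TSSSet, TSSSet]:
    """Partition TSSs into gene-proximal vs putative enhancer TSSs.

    A TSS is an enhancer TSS iff its distance to the nearest gene TSS is
    strictly greater than ``min_distance_bp``.  With no gene TSSs at all,
    every record is classed enhancer (with a warning).
    """
    if len(gene_tss) == 0:
        warnings.warn("no gene TSSs supplied; all TSSs classed as enhancer", stacklevel=2)
        return TSSSet(f"{all_tss.label}_gene_proximal", []), TSSSet(
            f"{all_tss.label}_enhancer", all_tss.intervals
        )
    dist = interval_to_point_distance(all_tss, gene_tss)
    enhancer_mask = dist > min_distance_bp
    proximal = [iv for iv, m in zip(all_tss, enhancer_mask) if not m]
    enhancer = [iv for iv, m in zip(all_tss, enhancer_mask) if m]
    return (
        TSSSet(f"{all_tss.label}_gene_proximal", proximal),
        TSSSet(f"{all_tss.label}_enhancer", enhancer),
    )


def class_proximity_report(
    classified: Sequence[ClassifiedPeak],
    gene_tss: TSSSet,
    enhancer_tss: TSSSet,
    threshold_bp: int = 1000,
) -> pd.DataFrame:
    """Per class: fraction of peaks within ``threshold_bp`` of each TSS set."""
    rows = []
    for c in CLASS_LABELS:
        ivs = [cp.interval for cp in classified if cp.gr_class == c]
        if not ivs:
            continue
        ps = PeakSet(f"class_{c}", ivs)
        frac_gene = frac_enh = 0.0
        if len(gene_tss):
            frac_gene = float(np.mean(interval_to_point_distance(ps, gene_tss) <= threshold_bp))
        if len(enhancer_tss):
            frac_enh = float(np.mean(interval_to_point_distance(ps, enhancer_tss) <= threshold_bp))
        rows.append(
            {"gr_class": c, "n": len(ps),
             "frac_within_gene_tss": frac_gene,
             "frac_within_enhancer_tss": frac_enh}
        )
    return pd.DataFrame(rows)


def _deg_tss_set(degs: pd.DataFrame) -> TSSSet:
    records = [
        GenomicInterval(str(r.chrom), int(r.tss), int(r.tss) + 1, str(r.gene_id),
                        0.0, r.strand if r.strand in ("+", "-") else ".")
        for r in degs.itertuples()
    ]
    return TSSSet("deg_tss", records)


def deg_peak_linkage(
    degs: pd.DataFrame,
    classified: Sequence[ClassifiedPeak],
    radius_bp: int = 50_000,
) -> "DEGProximity":
    """Closest GR peak (distance + class) and 50-kb peak count per gene.

    ``degs`` must carry gene_id/chrom/tss columns plus a ``category``
    column (common/lost/gained/neither).  Genes on chromosomes without any
    GR peak get a missing distance and a zero count.  Per-category median
    distances and pairwise rank-sum p-values on the distance distributions
    are included in the result.
    """
    if "category" not in degs.columns:
        raise ValueError("degs must carry a 'category' column")
    tss = _deg_tss_set(degs)
    gr = PeakSet("GR", [cp.interval for cp in classified])
    # map sorted-GR index -> class label
    sorted_cls = [cp.gr_class for cp in sorted(classified, key=lambda c: c.interval.sort_key())]
    nearest = closest_distance(tss, gr)
    counts = count_within(tss, gr, radius_bp)
    # tss set is sorted; map back to input row order via names
    order = {iv.name: i for i, iv in enumerate(tss)}
    rows = []
    for r in degs.itertuples():
        i = order[str(r.gene_id)]
        res = nearest[i]
        rows.append(
            {"gene_id": r.gene_id, "category": r.category,
             "distance_bp": float(res.distance_bp) if res.nearest_index is not None else np.nan,
             "closest_class": sorted_cls[res.nearest_index] if res.nearest_index is not None else None,
             "n_within_radius": int(counts[i])}
        )
    table = pd.DataFrame(rows)
    medians = (
        table.dropna(subset=["distance_bp"])
        .groupby("category")["distance_bp"].median().to_dict()
    )
    pvals: dict[tuple[str, str], float] = {}
    cats = [c for c in DEG_CATEGORIES if c != "neither" and (table["category"] == c).any()]
    for i, c1 in enumerate(cats):
        for c2 in cats[i + 1:]:
            d1 = table.loc[table["category"] == c1, "distance_bp"].dropna()
            d2 = table.loc[table["category"] == c2, "distance_bp"].dropna()
            if len(d1) and len(d2):
                pvals[(c1, c2)] = rank_sum_test(d1, d2).p_value
    return DEGProximity(table, medians, pvals, radius_bp)


@dataclass
class DEGProximity:
    table: pd.DataFrame
    category_medians: dict[str, float]
    pairwise_pvalues: dict[tuple[str, str], float]
    radius_bp: int

    def log10_distances(self) -> pd.Series:
        """log10(distance + 1 bp pseudo-distance), NaN-safe."""
        return np.log10(self.table["distance_bp"] + 1.0)


def deg_fraction_with_peaks(
    degs: pd.DataFrame,
    classified: Sequence[ClassifiedPeak],
    radius_bp: int = 50_000,
) -> tuple[float, float, float]:
    """(fraction of DEGs, fraction of non-DEGs) with >= 1 GR peak within radius.

    DEG status is the wild-type contrast (categories common + lost); the
    remaining genes in the shared universe are the non-DEG group.  Returns
    the two fractions and their ratio.
    """
    if "category" not in degs.columns:
        raise ValueError("degs must carry a 'category' column")
    is_deg = degs["category"].isin(["common", "lost"]).to_numpy()
    if is_deg.all() or not is_deg.any():
        raise ValueError("both DEG and non-DEG groups must be nonempty")
    tss = _deg_tss_set(degs)
    gr = PeakSet("GR", [cp.interval for cp in classified])
    counts = count_within(tss, gr, radius_bp)
    order = {iv.name: i for i, iv in enumerate(tss)}
    has_peak = np.asarray([counts[order[str(g)]] > 0 for g in degs["gene_id"]])
    frac_deg = float(has_peak[is_deg].mean())
    frac_non = float(has_peak[~is_deg].mean())
    ratio = frac_deg / frac_non if frac_non > 0 else np.inf
    return frac_deg, frac_non, ratio
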