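"""Enhancer-TSS definition, per-class proximity and DEG-peak linkage."""

import numpy as np
import pandas as pd
import pytest

from grbs import (
    GenomicInterval,
    TSSSet,
    class_proximity_report,
    classify_gr_peaks,
    deg_fraction_with_peaks,
    deg_peak_linkage,
    split_enhancer_tss,
)
from grbs.classify import ClassifiedPeak

from oracles import brute_interval_to_point, brute_point_to_interval


def tss(positions, chrom="chr1", label="t"):
    return TSSSet(label, [GenomicInterval(chrom, p, p + 1, f"{label}{i}")
                          for i, p in enumerate(positions)])


class TestSplitEnhancerTss:
    def test_strict_two_kb_boundary(self):
        gene = tss([10_000], label="gene")
        candidates = tss([11_000, 12_000, 12_001], label="all")
        proximal, enhancer = split_enhancer_tss(candidates, gene)
        # 1,000 and exactly 2,000 bp away stay gene-proximal; 2,001 is enhancer
        assert [iv.start for iv in proximal] == [11_000, 12_000]
        assert [iv.start for iv in enhancer] == [12_001]

    def test_partition_is_complete_and_disjoint(self, rng):
        gene = tss(sorted(rng.integers(0, 100_000, 30)), label="gene")
        candidates = tss(sorted(rng.integers(0, 100_000, 200)), label="all")
        proximal, enhancer = split_enhancer_tss(candidates, gene)
        assert len(proximal) + len(enhancer) == len(candidates)
        starts = {iv.start for iv in proximal} | {iv.start for iv in enhancer}
        assert starts == {iv.start for iv in candidates}

    def test_empty_gene_tss_all_enhancer(self):
        candidates = tss([100, 200])
        with pytest.warns(UserWarning, match="no gene TSS"):
            proximal, enhancer = split_enhancer_tss(candidates, tss([], label="gene"))
        assert len(proximal) == 0 and len(enhancer) == 2

    def test_matches_brute_force_nearest_gene_scan(self, rng):
        gene_positions = sorted(rng.integers(0, 50_000, 40))
        gene = tss(gene_positions, label="gene")
        candidates = tss(sorted(rng.integers(0, 50_000, 300)), label="all")
        _, enhancer = split_enhancer_tss(candidates, gene, 2000)
        expected = {
            iv.start for iv in candidates
            if min(abs(iv.start - g) for g in gene_positions) > 2000
        }
        assert {iv.start for iv in enhancer} == expected


class TestClassProximityReport:
    def make_classified(self, starts_by_class):
        out = []
        flags = {"I": (False, False), "II": (True, True), "III": (False, True)}
        for cls, starts in starts_by_class.items():
            e, d = flags[cls]
            for s in starts:
                out.append(ClassifiedPeak(GenomicInterval("chr1", s, s + 200), e, d, cls))
        return out

    def test_hand_fixture_half_within(self):
        classified = self.make_classified(
            {"II": [1000, 5000, 50_000, 60_000]}
        )
        gene = tss([1500, 5500])  # within 1 kb of the first two peaks only
        rep = class_proximity_report(classified, gene, tss([], label="e"))
        row = rep.set_index("gr_class").loc["II"]
        assert row["frac_within_gene_tss"] == pytest.approx(0.5)
        assert row["frac_within_enhancer_tss"] == 0.0

    def test_fraction_monotone_in_threshold(self, rng):
        classified = self.make_classified(
            {"I": sorted(rng.integers(0, 200_000, 40))}
        )
        gene = tss(sorted(rng.integers(0, 200_000, 20)))
        fracs = [
            class_proximity_report(classified, gene, tss([], label="e"), t)
            .set_index("gr_class").loc["I", "frac_within_gene_tss"]
            for t in (100, 1000, 10_000, 100_000)
        ]
        assert fracs == sorted(fracs)

    def test_planted_enhancer_ordering_recovered(self, small_dataset):
        ds = small_dataset
        classified = classify_gr_peaks(ds.gr, ds.brg1_etoh, ds.brg1_dex)
        rep = class_proximity_report(
            classified, ds.gene_tss, ds.enhancer_tss["EtOH"]
        ).set_index("gr_class")
        col = rep["frac_within_enhancer_tss"]
        assert col["II"] > col["III"] > col["I"]


def _degs_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand",
                                       "log2fc", "pvalue", "fdr", "category"])


class TestDegPeakLinkage:
    def test_single_peak_distance(self):
        classified = [ClassifiedPeak(GenomicInterval("chr1", 16_000, 16_500),
                                     False, False, "I")]
        degs = _degs_frame([("g1", "chr1", 10_000, "+", 2.0, 1e-4, 1e-3, "common")])
        link = deg_peak_linkage(degs, classified)
        row = link.table.iloc[0]
        assert row["distance_bp"] == 6000 and row["closest_class"] == "I"
        assert row["n_within_radius"] == 1

    def test_no_peaks_on_chromosome(self):
        classified = [ClassifiedPeak(GenomicInterval("chr2", 0, 100), False, False, "I")]
        degs = _degs_frame([("g1", "chr1", 5000, "+", 2.0, 1e-4, 1e-3, "common")])
        link = deg_peak_linkage(degs, classified)
        row = link.table.iloc[0]
        assert np.isnan(row["distance_bp"]) and row["n_within_radius"] == 0

    def test_distances_match_brute_force(self, rng):
        ivs = [GenomicInterval("chr1", int(s), int(s) + 300)
               for s in sorted(rng.integers(0, 500_000, 50))]
        classified = [ClassifiedPeak(iv, False, False, "I") for iv in ivs]
        degs = _degs_frame([
            (f"g{i}", "chr1", int(p), "+", 2.0, 1e-4, 1e-3, "common")
            for i, p in enumerate(rng.integers(0, 500_000, 80))
        ])
        link = deg_peak_linkage(degs, classified)
        for _, row in link.table.iterrows():
            p = int(degs.loc[degs["gene_id"] == row["gene_id"], "tss"].iloc[0])
            d, _ = brute_point_to_interval(p, "chr1", ivs)
            assert row["distance_bp"] == d

    def test_planted_category_ordering(self, small_dataset):
        ds = small_dataset
        classified = classify_gr_peaks(ds.gr, ds.brg1_etoh, ds.brg1_dex)
        degs = ds.wt_table.copy()
        degs["category"] = degs["gene_id"].map(ds.truth.gene_category)
        link = deg_peak_linkage(degs, classified)
        med = link.category_medians
        assert med["common"] < med["lost"]
        assert med["common"] < med["gained"]
        assert ("common", "lost") in link.pairwise_pvalues

    def test_log10_pseudo_distance(self):
        classified = [ClassifiedPeak(GenomicInterval("chr1", 5000, 5100),
                                     False, False, "I")]
        degs = _degs_frame([("g1", "chr1", 5050, "+", 2.0, 1e-4, 1e-3, "common")])
        link = deg_peak_linkage(degs, classified)
        assert link.log10_distances().iloc[0] == 0.0   # log10(0 + 1)


class TestDegFractionWithPeaks:
    def test_hand_fixture(self):
        classified = [ClassifiedPeak(GenomicInterval("chr1", 9_000, 9_400),
                                     False, False, "I")]
        rows = [(f"d{i}", "chr1", 10_000 + i, "+", 2.0, 1e-4, 1e-3, "common")
                for i in range(3)]
        rows += [("d3", "chr2", 10, "+", 2.0, 1e-4, 1e-3, "lost")]
        rows += [(f"n{i}", "chr2", 1000 + i, "+", 0.0, 0.5, 0.9, "neither")
                 for i in range(3)]
        rows += [("n3", "chr1", 11_000, "+", 0.0, 0.5, 0.9, "neither")]
        frac_deg, frac_non, ratio = deg_fraction_with_peaks(_degs_frame(rows), classified)
        assert frac_deg == pytest.approx(0.75)
        assert frac_non == pytest.approx(0.25)
        assert ratio == pytest.approx(3.0)

    def test_single_group_rejected(self):
        classified = [ClassifiedPeak(GenomicInterval("chr1", 0, 100), False, False, "I")]
        degs = _degs_frame([("g1", "chr1", 50, "+", 2.0, 1e-4, 1e-3, "common")])
        with pytest.raises(ValueError):
            deg_fraction_with_peaks(degs, classified)

    def test_planted_enrichment_ratio_above_two(self, sparse_dataset):
        ds = sparse_dataset
        classified = classify_gr_peaks(ds.gr, ds.brg1_etoh, ds.brg1_dex)
        degs = ds.wt_table.copy()
        degs["category"] = degs["gene_id"].map(ds.truth.gene_category)
        _, _, ratio = deg_fraction_with_peaks(degs, classified)
        assert ratio > 2.0
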