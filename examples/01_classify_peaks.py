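"""Partition GR peaks into BRG1 co-occupancy classes.

Builds a small synthetic dataset with planted class structure, classifies
every GR peak by its overlap with the vehicle- and hormone-condition BRG1
peak sets, and prints the class counts and width quartiles.
"""

from grbs import SimConfig, classify_gr_peaks, simulate_all, summarize_classes

cfg = SimConfig(seed=1, n_chroms=2, chrom_length_bp=400_000,
                peak_region_fraction=0.6, n_gr_peaks=150,
                n_background_brg1=30, n_genes=200)
ds = simulate_all(cfg, with_tracks=False)

classified = classify_gr_peaks(ds.gr, ds.brg1_etoh, ds.brg1_dex)
summary = summarize_classes(classified)

print("class counts:", summary.counts)
print("class fractions:", {c: round(f, 3) for c, f in summary.fractions.items()})
for cls, q in summary.width_quantiles.items():
    print(f"class {cls}: median width {q['median']:.0f} bp")
recovered = sum(cp.gr_class == t for cp, t in zip(classified, ds.truth.peak_class))
print(f"planted labels recovered: {recovered}/{len(ds.gr)}")

# Class I = no BRG1 overlap in either condition, Class II = BRG1 in both,
# Class III = hormone-specific BRG1 only.  On planted data recovery is exact
# because class semantics are guaranteed by construction; Class I peaks are
# planted narrower, which the width medians reflect.
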