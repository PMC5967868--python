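"""Meta-profiles and window tests of BRG1 coverage over Class III peaks.

Class III peaks gain BRG1 after hormone: the generator plants a 3x
Dex/vehicle amplitude ratio there, with Poisson-like noise, plus a
knockdown variant in which the hormone-induced gain is zeroed.
"""

import numpy as np

from grbs import (
    SimConfig, build_matrix, classify_gr_peaks, meta_profile, rank_sum_test,
    simulate_all, window_means,
)
from grbs.classify import class_subsets

cfg = SimConfig(seed=3, n_chroms=2, chrom_length_bp=500_000,
                peak_region_fraction=0.8, n_gr_peaks=300, n_background_brg1=30,
                class_mix={"I": 0.1, "II": 0.1, "III": 0.8, "other": 0.0},
                n_genes=50, track_factors=("BRG1",))
ds = simulate_all(cfg)
classified = classify_gr_peaks(ds.gr, ds.brg1_etoh, ds.brg1_dex)
p3 = class_subsets(classified)["III"]

def height(profile):
    c = len(profile) // 2
    flank = np.median(np.r_[profile[:10], profile[-10:]])
    return profile[c - 2:c + 2].mean() - flank

prof_e = meta_profile(build_matrix(ds.tracks[("BRG1", "EtOH")], p3))
prof_d = meta_profile(build_matrix(ds.tracks[("BRG1", "Dex")], p3))
print(f"Class III peaks: {len(p3)}")
print(f"meta-profile peak height: vehicle {height(prof_e):.2f}, "
      f"hormone {height(prof_d):.2f} (ratio {height(prof_d)/height(prof_e):.2f})")

for label, cond_pair in [("wild-type", ("EtOH", "Dex")),
                         ("knockdown", ("KD_EtOH", "KD_Dex"))]:
    a = window_means(ds.tracks[("BRG1", cond_pair[0])], p3)["mean_signal"]
    b = window_means(ds.tracks[("BRG1", cond_pair[1])], p3)["mean_signal"]
    res = rank_sum_test(a, b)
    print(f"{label}: rank-sum p = {res.p_value:.3g} on 500-bp window means")

# The wild-type contrast detects the planted 3x induction (tiny p); in the
# knockdown the induced amplitude delta is zeroed by construction, so the
# same test is a null comparison and p is large.
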