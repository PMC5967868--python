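# grbs — GR binding-site classes by BRG1 co-occupancy

`grbs` is a Python library and pipeline for a recurring analysis in hormone-response
epigenomics: partitioning glucocorticoid-receptor (GR) ChIP-seq peaks by whether the
SWI/SNF ATPase BRG1 co-occupies them **before** and/or **after** hormone
(dexamethasone, "Dex") treatment, and then characterizing the resulting classes.

With `G` the GR peak set (Dex condition) and `B_EtOH`, `B_Dex` the BRG1 peak sets in
vehicle and hormone conditions, each GR peak `g` is labelled from its ≥1-bp overlap
flags under half-open BED coordinates:

| class | definition | interpretation |
| --- | --- | --- |
| I   | `g ∩ B_EtOH = ∅` and `g ∩ B_Dex = ∅` | BRG1-free GR sites |
| II  | `g ∩ B_EtOH ≠ ∅` and `g ∩ B_Dex ≠ ∅` | constitutively BRG1-bound (pre-patterned, accessible) |
| III | `g ∩ B_EtOH = ∅` and `g ∩ B_Dex ≠ ∅` | hormone-induced BRG1 recruitment |
| other | `g ∩ B_EtOH ≠ ∅` only | small vehicle-only residual, kept explicit |

Around this partition the package provides:

- **genomic I/O** — BED6/narrowPeak, FASTA, 4-column bedGraph, TSV DE tables,
  gzip-transparent, strict validation (`grbs.formats`);
- **interval algebra** — sorted-sweep overlap flags, closest-feature distances,
  windowed counts/fractions (`grbs.engine`);
- **GRE motif scanning** — mismatch scan for the 15-bp inverted-repeat consensus
  `AGAACAnnnTGTTCT` (12 informative positions, fully degenerate 3-bp spacer),
  per-class perfect / single-mismatch fractions (`grbs.motifs`);
- **signal aggregation** — deeptools-style peaks×bins matrices, meta-profiles,
  500-bp window means, and the unpaired Wilcoxon rank-sum / Mann–Whitney test
  (exact enumeration for n₁+n₂ ≤ 20, tie-corrected normal approximation above)
  (`grbs.signal`);
- **TSS proximity** — enhancer-TSS definition (> 2 kb from any gene TSS, strict),
  per-class within-1-kb fractions, DEG-TSS→closest-peak distances and
  peaks-within-50-kb counts (`grbs.tss`);
- **DEG analysis** — calls at |fold change| > 1.5, p < 0.01, FDR < 0.05 (strict),
  common / lost / gained categories between wild-type and BRG1-knockdown
  contrasts, BH step-up helper (`grbs.deg`);
- **synthetic data** — a seeded generator that plants all of the above structure
  with recorded ground truth (`grbs.simulate`);
- **pipeline CLI** — `grbs simulate|classify|gre|signal|proximity|deg|report`
  over a single YAML config with provenance-stamped artifacts (`grbs.cli`).

## Worked example

`examples/01_classify_peaks.py` simulates a small dataset with planted class
structure and classifies it:

```
class counts: {'I': 61, 'II': 60, 'III': 29, 'other': 0}
class fractions: {'I': 0.407, 'II': 0.4, 'III': 0.193, 'other': 0.0}
class I: median width 253 bp
class II: median width 387 bp
class III: median width 349 bp
planted labels recovered: 150/150
```

Recovery is exact because the generator guarantees class semantics by
construction (guard spacing between peak slots); Class I peaks are planted
narrower, which the width medians reflect. The other scripts in `examples/`
walk through motif scanning, signal profiles with the knockdown null,
TSS/DEG linkage, and pioneer-factor splits, e.g. from
`examples/03_signal_profiles.py`:

```
Class III peaks: 240
meta-profile peak height: vehicle 0.89, hormone 2.75 (ratio 3.08)
wild-type: rank-sum p = 4.12e-80 on 500-bp window means
knockdown: rank-sum p = 0.934 on 500-bp window means
```

The planted 3× hormone induction of BRG1 at Class III peaks is recovered from
the noisy tracks, and the knockdown variant (induced delta zeroed) behaves as
a null.

## Command-line pipeline

```sh
grbs --config run.yaml --out results --seed 7 simulate
grbs --config run.yaml --out results --seed 7 classify
grbs --config run.yaml --out results --seed 7 gre
grbs --config run.yaml --out results --seed 7 deg
grbs --config run.yaml --out results --seed 7 proximity
grbs --config run.yaml --out results --seed 7 signal
grbs --config run.yaml --out results --seed 7 report
```

The YAML config has three optional sections: `simulate` (generator overrides),
`inputs` (paths to peak sets, genome, tracks, TSS BEDs and DE tables — defaults
point at the simulated fixture), and `thresholds` (proximity 1 kb, radius
50 kb, DEG cutoffs, motif consensus, window/bin geometry, and a
`tss_coordinates: 1-based` switch for 1-based TSS tables). Every artifact
carries a config-hash provenance header and stages refuse to mix artifacts
from different configs. Exit codes: 0 ok, 2 config error, 3 format error,
4 missing prerequisite.

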