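# Methods

## The analysis model

The package operationalizes a peak-set-level model of hormone-receptor /
chromatin-remodeler interplay. All coordinates are 0-based half-open (BED
convention); an interval's length is `end − start` and two intervals overlap
iff they share at least one base. Peak sets are immutable, sorted by
`(chrom, start, end)`, with per-chromosome coordinate arrays cached so that
overlap and distance queries run as binary searches / linear sweeps
(O((n+m) log m) after the one-time sort) rather than all-pairs scans. Every
optimized query has a brute-force oracle in the test suite.

### Classification

A GR peak's class is a pure function of two Boolean overlap flags (≥ 1 bp
against the full vehicle-condition and hormone-condition BRG1 sets):
I = neither, II = both, III = Dex only. The vehicle-only residual is kept as
an explicit `other` class rather than dropped or folded in: it is small but
real in any three-way overlap, and hiding it would break the partition
identity Σ counts = |GR set| that downstream stages rely on. "Dex-specific
BRG1" is evaluated at the GR-peak level (overlaps Dex ∧ ¬overlaps EtOH), not
by first computing a Dex-specific BRG1 subset; the two formulations agree
for the class definitions while avoiding BRG1-peak-level matching.

### Distances and proximity

Distances are unstranded. Point-to-interval distance is 0 inside the
interval, else the gap to the nearest covered base (`start` or `end − 1`).
"Within X of a TSS" is peak-edge to TSS-point under the same rule. Ties
between an upstream and downstream nearest neighbour resolve to the lower
start coordinate, making outputs deterministic. `count_within` anchors
subject peaks at their narrowPeak summit when present, else the midpoint,
so a 50-kb radius counts each peak once regardless of its width. Enhancer
TSSs are actively transcribed start sites strictly more than 2 kb from any
gene TSS. log10 distance reporting adds a 1-bp pseudo-distance so zero
distances remain finite.

### Motif model

The default GRE is the canonical inverted repeat `AGAACAnnnTGTTCT`: two 6-bp
half-sites on opposite strands around a fully degenerate 3-bp spacer. A
window's mismatch count is taken over the 12 informative positions only; an
`N` in the genome always counts as a mismatch there (conservative), and the
spacer never does. Because the default consensus equals its own reverse
complement, a forward-strand scan enumerates every genomic occurrence
exactly once; a user-supplied non-palindromic consensus is scanned on both
strands. `scan_sequence` reports all (overlapping) hits; only
`best_hit_per_peak` collapses, preferring fewest mismatches then leftmost
position. Two search modes reflect two distinct questions: the full peak
span ("does this peak contain a GRE?") and a ±500 bp window around the peak
centre (summit when present); both are exposed.

### Signal aggregation

Heatmap matrices are peaks × bins of mean per-base coverage in windows of
± 2,000 bp around the anchor, 25-bp bins by default (configurable; the
window/bin geometry is a display convention, not a statistical choice).
Windows clipped at chromosome ends average only in-bounds bases — zero
padding would bias edge rows downward. No between-sample normalization is
applied; tracks are assumed depth-normalized upstream, and a per-track
scale factor (`CoverageTrack.scaled`) is available. Meta-profiles are
column means (median offered). Window statistics use the mean per-base
signal in a fixed 500-bp window centred on the peak centre.

### Rank-sum test

The two-group comparison throughout is the unpaired two-sided Wilcoxon
rank-sum / Mann–Whitney test. For n₁+n₂ ≤ 20 the p-value is computed by
exact enumeration of all C(n₁+n₂, n₁) group assignments on midranks, which
remains valid under ties (the reason a bespoke exact path exists at all);
larger samples use the tie-corrected normal approximation with a 0.5
continuity correction via scipy. Two groups that are a single identical
value return p = 1 with a warning. Calibration is verified by simulation:
10,000 null replicates at n = 50 per group give a type-I error within
[0.043, 0.057] at α = 0.05.

### Differential expression

The package consumes DE statistics (gene, TSS coordinate, log2FC, p, FDR)
rather than fitting an expression model. A gene is a DEG when
|log2FC| > log2 1.5 and p < 0.01 and FDR < 0.05, all strict, applied to raw
(unshrunken) fold changes. The wild-type/knockdown cross-tabulation yields
common / lost / gained / neither; gene universes are outer-joined with
absent-means-not-DEG (warned), since a shared universe is implied by the
design. The BH helper is the standard step-up
(q₍ᵢ₎ = min over j ≥ i of p₍ⱼ₎·n/j, capped at 1, returned in input order),
delegated to statsmodels and checked in tests against a literal min-scan
implementation.

## The synthetic-data generator

The generator produces internally consistent inputs whose planted structure
is recorded as ground truth, so every downstream stage can be scored without
re-derivation. It emulates:

- **three-way co-occupancy** — GR/BRG1 peaks are laid out on a jittered slot
  grid with guard spacing; the BRG1 intervals each class requires are
  co-located within the slot, and background BRG1 peaks (vehicle-only,
  Dex-only, or both) occupy GR-free slots. Labels are therefore exact by
  construction, not by rejection sampling, which makes 100% recovery a
  meaningful test rather than a tautology.
- **peak territory** — all peaks are confined to the 5' 30% of each
  chromosome. This is the desk-scale analogue of binding-site clustering on
  a real genome: a uniformly placed gene then has a realistic (~30%) chance
  of having no peak within 50 kb, which is what gives the DEG-vs-non-DEG
  contrast its meaning. Without it, 1,000 peaks on 10 Mb put a peak within
  50 kb of *every* gene.
- **GRE content** — perfect GREs are written into the genome at peak anchors
  with class-specific probabilities (0.33 / 0.19 / 0.35 for I / II / III),
  single-mismatch GREs (one random informative position mutated) at 0.51
  for all classes. The uniform background contributes ~10⁻³ spurious hits
  per peak, negligible against the 3-binomial-SE recovery tolerance.
- **coverage** — per-peak Gaussian bumps (σ = 100 bp) on a flat baseline
  (0.2 reads/bp), amplitudes per factor/condition/class: GR appears only
  after hormone and is weaker at Class I; BRG1 is constitutive at II,
  induced 1 → 3 at III, vehicle-only at `other`. Counts are Poisson per
  10-bp block (variance ≈ mean, as for binned read coverage) and expressed
  as reads per base. Knockdown tracks replace every Dex amplitude with its
  vehicle value, so the hormone contrast becomes an exact null.
- **TSSs and DE tables** — gene TSSs for DEG-category genes sit at a
  lognormal planted distance from the edge of a random GR peak (median
  300 / 900 / 1,000 bp for common / gained / lost, σ_log = 0.4); `neither`
  genes are uniform over the genome. The planted medians are deliberately
  ~20× smaller than their real-genome analogues: at the desk-scale peak
  pitch (~2.5 kb) any planted distance beyond half the pitch would be
  shadowed by an unrelated neighbouring peak and the ordering would be
  unrecoverable, so the *ordering*, not the magnitude, is the invariant
  carried over. Enhancer TSSs are planted within 1 kb of peaks at
  class/condition-specific rates (vehicle: 0.38 / 0.07 / 0.02 for
  II / III / I) plus 50 uniform background TSSs. Observed log2FC is the
  planted effect (|effect| ≥ 4× the log2 1.5 cutoff, shared sign across
  contrasts, exponential jitter) plus N(0, 0.05) noise; p-values follow
  from the known-variance normal model (null p-values are exactly uniform)
  and FDR from the BH helper. With these margins, category recovery is
  exact up to astronomically unlikely tails.

Default problem sizes — 5 × 2 Mb chromosomes, 1,000 GR + 200 background
BRG1 peaks, 2,000 genes — keep a full simulation-plus-analysis cycle in
seconds while leaving every recovery statistic well-powered; tests that need
many replicates (knockdown nulls, ordering stability across 20 seeds) use
proportionally smaller configs with the same structure.

All randomness flows from a single integer seed through independent
`numpy` PCG64 substreams per stage, so identical configs give byte-identical
outputs across runs and platforms.

### What the generator does *not* emulate

Read-level artifacts (fragment-length distributions, GC and mappability
bias), peak-calling uncertainty (peaks are exact by construction, never
miscalled), correlated replicate structure, realistic non-uniform genome
composition, and expression count models (DE statistics are generated
directly, not via a count model). Passing recovery tests therefore
demonstrates that the analysis logic is correct and calibrated under the
stated noise model — not that it is robust to upstream artifacts real data
would add.

## Numerical and degenerate-input choices

- bedGraph inputs with overlapping runs are rejected outright; silently
  summing would corrupt window means.
- Empty BRG1 sets are valid classification inputs (degenerate: no peak can
  be II/III); an empty GR set is an error, as is an empty query set for a
  fraction (undefined).
- narrowPeak summit −1 means "absent"; downstream anchors fall back to the
  interval midpoint.
- Chromosome names match exactly; no "chr" aliasing is attempted.
- p-values from the normal model are clipped to [1e-300, 1] to stay inside
  (0, 1].
- Fractions over an empty class are omitted (with a warning) rather than
  reported as NaN.

## Known limitations

- The interval engine holds dense per-base coverage in memory
  (float32; ~4 MB per 1 Mb of genome per track), appropriate for desk-scale
  and single-chromosome work, not whole-genome multi-track sessions.
- The exact rank-sum path enumerates all assignments and is only engaged up
  to n₁+n₂ = 20 by design.
- TSS records are treated independently; no strand-collapsing of bidirectional
  start sites is attempted.
- The motif module scores exact-mismatch counts against a consensus; it is
  not a PWM scanner and does not compute enrichment p-values.
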