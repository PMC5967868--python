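"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the structure of a hormone-response
ChIP-seq study: GR peaks partitioned into BRG1 co-occupancy classes by
construction, a GRE consensus written under peak centres at class-specific
rates, coverage tracks with class- and condition-specific bump amplitudes
(plus a knockdown variant whose hormone-induced gains are zeroed), gene and
enhancer TSSs placed relative to peaks, and differential-expression tables
with planted common/lost/gained genes.

Peaks are laid out on a regular slot grid confined to a "peak territory" at
the 5' end of each chromosome, with guard spacing between slots, so every
planted class label is unambiguous by construction and the remainder of the
genome is peak-free (mirroring the clustering of binding sites in real
genomes and giving uniformly placed genes a realistic chance of having no
peak within tens of kb).

Everything is driven by a single integer seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .deg import bh_fdr
from .formats import (
    Genome,
    write_bed,
    write_bedgraph,
    write_de_table,
    write_fasta,
)
from .intervals import GenomicInterval, PeakSet, TSSSet
from .motifs import DEFAULT_GRE, MotifModel
from .signal import CoverageTrack

CLASSES = ("I", "II", "III", "other")
BG_CONDITIONS = ("EtOH", "Dex", "both")


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_class_mix() -> dict[str, float]:
    # echoes the observed three-way split: ~41% BRG1-free, ~40% constitutive,
    # ~19% hormone-specific
    return {"I": 0.41, "II": 0.40, "III": 0.19, "other": 0.0}


def _default_widths() -> dict[str, tuple[float, float]]:
    # Class I peaks run narrower than BRG1-co-occupied classes
    return {"I": (250.0, 40.0), "II": (400.0, 60.0), "III": (350.0, 50.0),
            "other": (300.0, 50.0)}


def _default_gre_rates() -> dict[str, float]:
    # perfect-GRE planting: highest in Classes I and III, depleted in II
    return {"I": 0.33, "II": 0.19, "III": 0.35, "other": 0.28}


def _default_gre_1mm_rates() -> dict[str, float]:
    return {"I": 0.51, "II": 0.51, "III": 0.51, "other": 0.51}


def _default_signal_model() -> dict[str, dict[str, dict[str, float]]]:
    # bump amplitudes (reads per base above baseline) per factor/condition/class:
    # GR binds only after hormone and is weaker at Class I; BRG1 is
    # constitutive at Class II, hormone-induced at Class III (EtOH->Dex
    # amplitude ratio 3), vehicle-only at "other"
    return {
        "GR": {
            "EtOH": {"I": 0.0, "II": 0.0, "III": 0.0, "other": 0.0},
            "Dex": {"I": 2.0, "II": 4.0, "III": 4.0, "other": 2.0},
        },
        "BRG1": {
            "EtOH": {"I": 0.0, "II": 4.0, "III": 1.0, "other": 3.0},
            "Dex": {"I": 0.0, "II": 4.0, "III": 3.0, "other": 0.0},
        },
    }


def _default_deg_mix() -> dict[str, float]:
    # 30/60/10 among the planted DEG pool, pool = 25% of genes
    return {"common": 0.075, "lost": 0.15, "gained": 0.025, "neither": 0.75}


def _default_effect_sizes() -> dict[str, tuple[float, float]]:
    # (|log2FC| in wild-type, in knockdown); >= 4x the log2(1.5) cutoff so
    # planted categories are recovered exactly
    return {"common": (2.4, 1.9), "lost": (2.4, 0.0), "gained": (0.0, 2.4),
            "neither": (0.0, 0.0)}


def _default_tss_distance_medians() -> dict[str, float]:
    # median planted peak-edge -> gene-TSS distance per DEG category;
    # scaled to the desk-scale peak pitch, ordering common < gained < lost
    return {"common": 300.0, "gained": 900.0, "lost": 1000.0}


def _default_enh_tss_rates() -> dict[str, dict[str, float]]:
    # probability of an active enhancer TSS within 1 kb of a peak,
    # per condition and class (vehicle: II >> III > I)
    return {
        "EtOH": {"I": 0.02, "II": 0.38, "III": 0.07, "other": 0.05},
        "Dex": {"I": 0.26, "II": 0.45, "III": 0.38, "other": 0.05},
    }


@dataclass
class SimConfig:
    """Everything the generator needs; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 5
    chrom_length_bp: int = 2_000_000
    peak_region_fraction: float = 0.3
    n_gr_peaks: int = 1000
    n_background_brg1: int = 200
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    peak_width_bp: dict[str, tuple[float, float]] = field(default_factory=_default_widths)
    brg1_width_bp: tuple[float, float] = (500.0, 60.0)
    gre_rate: dict[str, float] = field(default_factory=_default_gre_rates)
    gre_1mm_rate: dict[str, float] = field(default_factory=_default_gre_1mm_rates)
    signal_model: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=_default_signal_model
    )
    bg_brg1_amplitude: float = 3.0
    bump_sd_bp: float = 100.0
    baseline_signal: float = 0.2
    track_resolution_bp: int = 10
    track_factors: tuple[str, ...] = ("GR", "BRG1")
    kd_factors: tuple[str, ...] = ("BRG1",)
    n_genes: int = 2000
    deg_mix: dict[str, float] = field(default_factory=_default_deg_mix)
    effect_sizes: dict[str, tuple[float, float]] = field(default_factory=_default_effect_sizes)
    effect_jitter_scale: float = 0.3
    lfc_noise_sd: float = 0.05
    tss_distance_medians: dict[str, float] = field(
        default_factory=_default_tss_distance_medians
    )
    tss_distance_sigma: float = 0.4
    enh_tss_rates: dict[str, dict[str, float]] = field(default_factory=_default_enh_tss_rates)
    enh_tss_max_offset_bp: int = 900
    n_background_enhancer_tss: int = 50
    motif: MotifModel = DEFAULT_GRE

    def validate(self) -> None:
        for name, mix in (("class_mix", self.class_mix), ("deg_mix", self.deg_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise SimConfigError(f"{name} proportions must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise SimConfigError(f"{name} proportions must be >= 0")
        for name, rates in (("gre_rate", self.gre_rate), ("gre_1mm_rate", self.gre_1mm_rate)):
            for c, v in rates.items():
                if not 0 <= v <= 1:
                    raise SimConfigError(f"{name}[{c}] must lie in [0, 1]")
        for c in CLASSES:
            if self.gre_rate.get(c, 0) + self.gre_1mm_rate.get(c, 0) > 1:
                raise SimConfigError(f"gre_rate + gre_1mm_rate exceed 1 for class {c}")
        for c, (mean, sd) in self.peak_width_bp.items():
            if mean <= 0 or sd < 0:
                raise SimConfigError(f"peak_width_bp[{c}] must be positive")
        if not 0 < self.peak_region_fraction <= 1:
            raise SimConfigError("peak_region_fraction must lie in (0, 1]")
        if self.n_chroms < 1 or self.chrom_length_bp < 10_000:
            raise SimConfigError("need >= 1 chromosome of >= 10 kb")
        if self.track_resolution_bp < 1:
            raise SimConfigError("track_resolution_bp must be >= 1")
        if self.seed < 0:
            raise SimConfigError("seed must be a nonnegative integer")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class GroundTruth:
    """Planted facts, sufficient to score every downstream stage."""

    peak_class: list[str] = field(default_factory=list)       # aligned with GR set
    gre_status: list[str] = field(default_factory=list)       # perfect/one_mismatch/none
    bg_brg1: list[tuple[str, int, str]] = field(default_factory=list)  # chrom, anchor, cond
    gene_category: dict[str, str] = field(default_factory=dict)
    true_log2fc: dict[str, tuple[float, float]] = field(default_factory=dict)  # wt, kd

    def to_json(self) -> str:
        return json.dumps(
            {
                "peak_class": self.peak_class,
                "gre_status": self.gre_status,
                "bg_brg1": self.bg_brg1,
                "gene_category": self.gene_category,
                "true_log2fc": self.true_log2fc,
            }
        )


def _exact_counts(n: int, mix: dict[str, float], keys: Sequence[str]) -> dict[str, int]:
    """Largest-remainder apportionment of n items over mix proportions."""
    raw = {k: n * mix.get(k, 0.0) for k in keys}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_genome(config: SimConfig) -> Genome:
    """Uniform i.i.d. ACGT background of the configured dimensions."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {}
    for chrom in config.chrom_names():
        arr = rng.integers(0, 4, size=config.chrom_length_bp)
        sequences[chrom] = bases[arr].tobytes().decode("ascii")
    return Genome(sequences)


@dataclass
class PeakSimResult:
    genome: Genome            # with planted GREs written in
    gr: PeakSet
    brg1_etoh: PeakSet
    brg1_dex: PeakSet
    truth: GroundTruth


def _plant_gre(
    seq: bytearray, anchor: int, model: MotifModel, mismatches: int, rng: np.random.Generator
) -> None:
    motif = list(model.consensus)
    alphabet = "ACGT"
    for i, b in enumerate(motif):
        if b == "N":
            motif[i] = alphabet[rng.integers(0, 4)]
    if mismatches:
        informative = model.informative_positions
        pos = informative[rng.integers(0, len(informative))]
        alternatives = [b for b in alphabet if b != motif[pos]]
        motif[pos] = alternatives[rng.integers(0, 3)]
    start = anchor - model.length // 2
    seq[start:start + model.length] = "".join(motif).encode("ascii")


def simulate_peaks(config: SimConfig, genome: Genome) -> PeakSimResult:
    """Plant GR/BRG1 peaks with guaranteed class semantics and GREs.

    Slots are spaced so intervals from different slots can never touch;
    within a GR slot the BRG1 intervals required by the planted class are
    co-located with the GR interval, so classification labels are exact by
    construction.  GREs are written into the genome at GR peak anchors at
    the class-specific perfect / one-mismatch rates.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    chroms = config.chrom_names()
    territory = int(config.chrom_length_bp * config.peak_region_fraction)
    margin = 1000
    n_slots = config.n_gr_peaks + config.n_background_brg1
    per_chrom = [n_slots // len(chroms)] * len(chroms)
    for i in range(n_slots - sum(per_chrom)):
        per_chrom[i] += 1

    max_gr_w = max(m + 4 * s for m, s in config.peak_width_bp.values())
    max_brg1_w = config.brg1_width_bp[0] + 4 * config.brg1_width_bp[1]
    max_span = max(max_gr_w, max_brg1_w + 100)

    # roles, shuffled over the global slot grid
    class_counts = _exact_counts(config.n_gr_peaks, config.class_mix, CLASSES)
    roles: list[tuple[str, str]] = []
    for c in CLASSES:
        roles += [("gr", c)] * class_counts[c]
    for i in range(config.n_background_brg1):
        roles.append(("bg", BG_CONDITIONS[i % 3]))
    roles = [roles[i] for i in rng.permutation(len(roles))]

    seqs = {c: bytearray(genome.sequences[c], "ascii") for c in chroms}
    gr_records: list[tuple[GenomicInterval, str, str]] = []   # interval, class, gre
    brg1_etoh_ivs: list[GenomicInterval] = []
    brg1_dex_ivs: list[GenomicInterval] = []
    bg_brg1: list[tuple[str, int, str]] = []

    def draw_width(mean: float, sd: float, lo: float) -> int:
        return int(np.clip(rng.normal(mean, sd), lo, mean + 4 * sd))

    slot_cursor = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        usable = territory - 2 * margin
        pitch = usable / n_here
        jitter = min(400, int(pitch / 8))
        if pitch < max_span + 2 * jitter + 200:
            raise SimConfigError(
                f"infeasible packing: {n_here} slots on a "
                f"{territory} bp territory of {chrom} (pitch {pitch:.0f} bp, "
                f"need >= {max_span + 2 * jitter + 200:.0f})"
            )
        for i in range(n_here):
            center = int(margin + (i + 0.5) * pitch) + int(rng.integers(-jitter, jitter + 1))
            kind, detail = roles[slot_cursor]
            slot_cursor += 1
            if kind == "gr":
                cls = detail
                mean, sd = config.peak_width_bp[cls]
                w = draw_width(mean, sd, 100)
                start, end = center - w // 2, center - w // 2 + w
                summit = center - start
                gre = "none"
                u = rng.random()
                if u < config.gre_rate.get(cls, 0.0):
                    gre = "perfect"
                    _plant_gre(seqs[chrom], center, config.motif, 0, rng)
                elif u < config.gre_rate.get(cls, 0.0) + config.gre_1mm_rate.get(cls, 0.0):
                    gre = "one_mismatch"
                    _plant_gre(seqs[chrom], center, config.motif, 1, rng)
                gr_records.append(
                    (GenomicInterval(chrom, start, end, "", 0.0, ".", summit), cls, gre)
                )
                want_etoh = cls in ("II", "other")
                want_dex = cls in ("II", "III")
                for want, dest in ((want_etoh, brg1_etoh_ivs), (want_dex, brg1_dex_ivs)):
                    if want:
                        bw = draw_width(*config.brg1_width_bp, 150)
                        bc = center + int(rng.integers(-50, 51))
                        dest.append(GenomicInterval(chrom, bc - bw // 2, bc - bw // 2 + bw))
            else:
                cond = detail
                bw = draw_width(*config.brg1_width_bp, 150)
                iv = GenomicInterval(chrom, center - bw // 2, center - bw // 2 + bw)
                if cond in ("EtOH", "both"):
                    brg1_etoh_ivs.append(iv)
                if cond in ("Dex", "both"):
                    brg1_dex_ivs.append(iv)
                bg_brg1.append((chrom, center, cond))

    # gr_records were generated in (chrom, ascending-center) order == sorted
    gr_ivs = []
    truth = GroundTruth(bg_brg1=bg_brg1)
    for i, (iv, cls, gre) in enumerate(gr_records):
        gr_ivs.append(dataclasses.replace(iv, name=f"GR_{i:05d}"))
        truth.peak_class.append(cls)
        truth.gre_status.append(gre)

    mutated = Genome({c: seqs[c].decode("ascii") for c in chroms})
    return PeakSimResult(
        genome=mutated,
        gr=PeakSet("GR_Dex", gr_ivs),
        brg1_etoh=PeakSet("BRG1_EtOH", brg1_etoh_ivs),
        brg1_dex=PeakSet("BRG1_Dex", brg1_dex_ivs),
        truth=truth,
    )


def simulate_tracks(config: SimConfig, sim: PeakSimResult) -> dict[tuple[str, str], CoverageTrack]:
    """Coverage tracks with per-class Gaussian bumps and Poisson-like noise.

    Counts are drawn per ``track_resolution_bp`` block (variance tracks the
    mean, as for read-count coverage) and expressed as reads per base.  For
    every factor in ``kd_factors`` two knockdown tracks are added in which
    hormone-induced amplitude changes are zeroed (Dex amplitudes replaced
    by vehicle amplitudes).
    """
    config.validate()
    lengths = {c: config.chrom_length_bp for c in config.chrom_names()}
    anchors = [(iv.chrom, iv.anchor) for iv in sim.gr]
    classes = sim.truth.peak_class
    tracks: dict[tuple[str, str], CoverageTrack] = {}
    jobs: list[tuple[str, str, dict[str, float]]] = []
    for factor in config.track_factors:
        model = config.signal_model[factor]
        jobs.append((factor, "EtOH", model["EtOH"]))
        jobs.append((factor, "Dex", model["Dex"]))
        if factor in config.kd_factors:
            jobs.append((factor, "KD_EtOH", model["EtOH"]))
            jobs.append((factor, "KD_Dex", model["EtOH"]))  # induced delta zeroed
    r = config.track_resolution_bp
    sd = config.bump_sd_bp
    reach = int(4 * sd)
    for k, (factor, cond, amps) in enumerate(jobs):
        rng = np.random.default_rng([config.seed, 2, k])
        data = {}
        for chrom, length in lengths.items():
            n_bins = (length + r - 1) // r
            lam = np.full(n_bins, config.baseline_signal, dtype=np.float64)
            x = np.arange(n_bins, dtype=np.float64) * r + r / 2

            def add_bump(center: int, amp: float) -> None:
                if amp <= 0:
                    return
                b0 = max(0, (center - reach) // r)
                b1 = min(n_bins, (center + reach) // r + 1)
                lam[b0:b1] += amp * np.exp(-((x[b0:b1] - center) ** 2) / (2 * sd * sd))

            for (pc, anchor), cls in zip(anchors, classes):
                if pc == chrom:
                    add_bump(anchor, amps.get(cls, 0.0))
            is_brg1_like = factor in config.kd_factors or factor == "BRG1"
            if is_brg1_like:
                base_cond = "EtOH" if cond.endswith("EtOH") else "Dex"
                for bchrom, banchor, bcond in sim.truth.bg_brg1:
                    if bchrom == chrom and bcond in (base_cond, "both"):
                        add_bump(banchor, config.bg_brg1_amplitude)
            counts = rng.poisson(lam * r).astype(np.float32) / r
            data[chrom] = np.repeat(counts, r)[:length]
        tracks[(factor, cond)] = CoverageTrack(f"{factor}_{cond}", data)
    return tracks


@dataclass
class TSSDEGResult:
    gene_tss: TSSSet
    enhancer_tss: dict[str, TSSSet]   # condition -> set
    wt_table: pd.DataFrame
    kd_table: pd.DataFrame


def simulate_tss_and_degs(config: SimConfig, sim: PeakSimResult) -> TSSDEGResult:
    """Gene TSSs placed by DEG category, enhancer TSSs by peak class.

    DEG-category genes sit at a lognormal planted distance from the edge of
    a randomly chosen GR peak (common closest); "neither" genes are uniform
    over the genome, most of it peak-free.  Observed log2FC is the planted
    effect plus Gaussian noise; p-values come from the corresponding
    known-variance normal model, FDR from the BH step-up.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    chroms = config.chrom_names()
    L = config.chrom_length_bp
    cat_counts = _exact_counts(config.n_genes, config.deg_mix,
                               ("common", "lost", "gained", "neither"))
    cats: list[str] = []
    for c in ("common", "lost", "gained", "neither"):
        cats += [c] * cat_counts[c]
    cats = [cats[i] for i in rng.permutation(len(cats))]

    gr_ivs = sim.gr.intervals
    gene_rows = []
    for i, cat in enumerate(cats):
        gene_id = f"gene_{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if cat == "neither":
            chrom = chroms[rng.integers(0, len(chroms))]
            pos = int(rng.integers(0, L))
        else:
            iv = gr_ivs[rng.integers(0, len(gr_ivs))]
            d = int(rng.lognormal(math.log(config.tss_distance_medians[cat]),
                                  config.tss_distance_sigma))
            if rng.random() < 0.5:
                pos = iv.start - d
            else:
                pos = iv.end - 1 + d
            chrom = iv.chrom
            pos = int(np.clip(pos, 0, L - 1))
        wt_mag, kd_mag = config.effect_sizes[cat]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        jitter = rng.exponential(config.effect_jitter_scale)
        wt_true = sign * (wt_mag + jitter) if wt_mag > 0 else 0.0
        kd_true = sign * (kd_mag + jitter) if kd_mag > 0 else 0.0
        gene_rows.append((gene_id, cat, chrom, pos, strand, wt_true, kd_true))

    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "category", "chrom", "tss", "strand", "wt_true", "kd_true"],
    )
    sim.truth.gene_category = dict(zip(genes["gene_id"], genes["category"]))
    sim.truth.true_log2fc = {
        g: (float(w), float(k))
        for g, w, k in zip(genes["gene_id"], genes["wt_true"], genes["kd_true"])
    }

    def build_table(true_col: str) -> pd.DataFrame:
        obs = genes[true_col].to_numpy() + rng.normal(0, config.lfc_noise_sd, len(genes))
        z = np.abs(obs) / config.lfc_noise_sd
        p = np.clip(2 * _stats.norm.sf(z), 1e-300, 1.0)
        return pd.DataFrame(
            {"gene_id": genes["gene_id"], "chrom": genes["chrom"], "tss": genes["tss"],
             "strand": genes["strand"], "log2fc": obs, "pvalue": p, "fdr": bh_fdr(p)}
        )

    wt_table = build_table("wt_true")
    kd_table = build_table("kd_true")

    gene_tss = TSSSet(
        "gene_TSS",
        [GenomicInterval(r.chrom, r.tss, r.tss + 1, r.gene_id, 0.0, r.strand)
         for r in genes.itertuples()],
    )

    enhancer_tss = {}
    for cond in ("EtOH", "Dex"):
        records = []
        k = 0
        rates = config.enh_tss_rates[cond]
        for iv, cls in zip(sim.gr, sim.truth.peak_class):
            if rng.random() < rates.get(cls, 0.0):
                offset = int(rng.integers(0, config.enh_tss_max_offset_bp + 1))
                pos = iv.start - offset if rng.random() < 0.5 else iv.end - 1 + offset
                pos = int(np.clip(pos, 0, L - 1))
                records.append(
                    GenomicInterval(iv.chrom, pos, pos + 1, f"enh_{cond}_{k:05d}")
                )
                k += 1
        for _ in range(config.n_background_enhancer_tss):
            chrom = chroms[rng.integers(0, len(chroms))]
            pos = int(rng.integers(0, L))
            records.append(GenomicInterval(chrom, pos, pos + 1, f"enh_{cond}_{k:05d}"))
            k += 1
        enhancer_tss[cond] = TSSSet(f"enhancer_TSS_{cond}", records)

    return TSSDEGResult(gene_tss, enhancer_tss, wt_table, kd_table)


@dataclass
class SyntheticDataset:
    """A full, internally consistent set of inputs plus ground truth."""

    config: SimConfig
    genome: Genome
    gr: PeakSet
    brg1_etoh: PeakSet
    brg1_dex: PeakSet
    tracks: dict[tuple[str, str], CoverageTrack]
    gene_tss: TSSSet
    enhancer_tss: dict[str, TSSSet]
    wt_table: pd.DataFrame
    kd_table: pd.DataFrame
    truth: GroundTruth


def simulate_all(config: SimConfig, with_tracks: bool = True) -> SyntheticDataset:
    """Run every generator stage under one seed."""
    genome = simulate_genome(config)
    sim = simulate_peaks(config, genome)
    tracks = simulate_tracks(config, sim) if with_tracks else {}
    tss_deg = simulate_tss_and_degs(config, sim)
    return SyntheticDataset(
        config=config, genome=sim.genome, gr=sim.gr, brg1_etoh=sim.brg1_etoh,
        brg1_dex=sim.brg1_dex, tracks=tracks, gene_tss=tss_deg.gene_tss,
        enhancer_tss=tss_deg.enhancer_tss, wt_table=tss_deg.wt_table,
        kd_table=tss_deg.kd_table, truth=sim.truth,
    )


def write_fixture(dataset: SyntheticDataset, outdir) -> list[str]:
    """Write the dataset as standard files; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []

    def emit(name: str) -> Path:
        manifest.append(name)
        return outdir / name

    write_fasta(dataset.genome, emit("genome.fa"))
    write_bed(dataset.gr, emit("gr_dex.narrowPeak"), narrowpeak=True)
    write_bed(dataset.brg1_etoh, emit("brg1_etoh.bed"))
    write_bed(dataset.brg1_dex, emit("brg1_dex.bed"))
    for (factor, cond), track in dataset.tracks.items():
        write_bedgraph(track, emit(f"track_{factor}_{cond}.bedGraph".lower()))
    write_bed(dataset.gene_tss, emit("gene_tss.bed"))
    for cond, tset in dataset.enhancer_tss.items():
        write_bed(tset, emit(f"enhancer_tss_{cond.lower()}.bed"))
    write_de_table(dataset.wt_table, emit("de_wt.tsv"))
    write_de_table(dataset.kd_table, emit("de_kd.tsv"))
    (outdir / "truth.json").write_text(dataset.truth.to_json())
    manifest.append("truth.json")
    return manifest
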