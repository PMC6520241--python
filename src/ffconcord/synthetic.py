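"""Matched fresh-frozen / FFPE tumor pair simulator.

Generates the statistical structure the concordance analysis assumes: a
shared clonal truth set with subclonal divergence between the two specimens
of the same tumor, binomial read sampling at realistic depths, FFPE-only
cytosine-deamination (C>T) artifacts at low allelic fraction, overdispersed
and GC-biased FFPE coverage, and per-bin copy-number Log2 ratio tracks where
the FFPE track carries extra noise plus a low-frequency "wave".

Everything is driven by one :class:`SimulationConfig` and a single integer
seed; a fixed seed reproduces every draw bit for bit.

The two specimens model tissue taken from adjacent regions of the same
tumor block: clonal variants have identical true allelic fraction in both,
while a configurable fraction of subclonal variants is attenuated in one
specimen only (intratumor heterogeneity). Discordance between the observed
call sets then has exactly three sources - heterogeneity, binomial sampling
at finite depth, and FFPE artifacts - which is what the downstream metrics
are designed to separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageBin, VariantRecord
from .cna import CnaProfile

__all__ = [
    "SimulationConfig",
    "TumorTruthSet",
    "simulate_truth",
    "sample_observed_callsets",
    "replicate_callsets",
    "simulate_coverage",
    "simulate_cna_tracks",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# one representative ref/alt base pair per pyrimidine-context class
_CLASS_TO_ALLELES = {
    "C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
    "T>A": ("T", "A"), "T>C": ("T", "C"), "T>G": ("T", "G"),
}

# RNG stream ids so each stage draws independently of the others
_STREAM_TRUTH, _STREAM_CALLS, _STREAM_COV, _STREAM_CNA = 11, 12, 13, 14


def _default_chrom_lengths() -> dict[str, int]:
    return {"1": 120_000_000, "2": 80_000_000}


def _default_cna_segments() -> list[tuple[str, int, int, int]]:
    # one gain, one single-copy loss, one high-level amplification
    return [
        ("1", 10_000_000, 30_000_000, 3),
        ("1", 60_000_000, 80_000_000, 1),
        ("2", 20_000_000, 40_000_000, 4),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated FF/FFPE tumor pair.

    Depth defaults follow the measured means of the emulated study design
    (93x fresh-frozen, 77x FFPE against a 70x target; 30x normal). The FFPE
    dispersion multiplier of 3 sits inside the reported 1.1-5.8x range of
    coverage-SD inflation. Deamination rate is expressed as expected
    artifact count per megabase of simulated genome.
    """

    n_variants: int = 2000
    indel_fraction: float = 0.05
    depth_ff: float = 93.0
    depth_ffpe: float = 77.0
    depth_normal: float = 30.0
    purity: float = 0.8
    clonal_af_mode: float = 0.4
    clonal_concentration: float = 40.0
    subclone_fraction: float = 0.3
    subclone_af_alpha: float = 2.0
    subclone_af_beta: float = 18.0
    deamination_rate: float = 1.0          # artifacts per Mb, FFPE only
    artifact_af_alpha: float = 10.0
    artifact_af_beta: float = 150.0
    ffpe_dispersion_multiplier: float = 3.0
    gc_bias_strength: float = 1.0          # 0 disables the FFPE GC bias
    wave_amplitude: float = 0.3            # Log2R units
    wave_period: float = 5_000_000.0       # bases
    log2r_noise_sd_ff: float = 0.12
    log2r_noise_sd_ffpe: float = 0.25
    bin_size: int = 100_000
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    cna_segments: list[tuple[str, int, int, int]] = field(
        default_factory=_default_cna_segments)
    min_alt_reads: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")
        for name in ("depth_ff", "depth_ffpe", "depth_normal", "deamination_rate",
                     "wave_amplitude", "wave_period", "log2r_noise_sd_ff",
                     "log2r_noise_sd_ffpe", "gc_bias_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("purity", "clonal_af_mode", "subclone_fraction",
                     "indel_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {val}")
        if self.ffpe_dispersion_multiplier < 1.0:
            raise ValueError("ffpe_dispersion_multiplier must be >= 1")
        if self.bin_size <= 0 or self.min_alt_reads < 0:
            raise ValueError("bin_size must be > 0 and min_alt_reads >= 0")
        for chrom, start, end, cn in self.cna_segments:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"CNA segment on unknown chromosome {chrom!r}")
            if not 0 <= start < end <= self.chrom_lengths[chrom]:
                raise ValueError(f"invalid CNA segment {chrom}:{start}-{end}")
            if cn < 0:
                raise ValueError("copy number must be >= 0")

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_lengths.values())

    @property
    def n_bins(self) -> int:
        return sum(-(-length // self.bin_size)
                   for length in self.chrom_lengths.values())

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class TumorTruthSet:
    """True per-variant allelic fractions in both specimens.

    ``variants`` columns: chrom, pos, ref, alt, vclass, true_af_ff,
    true_af_ffpe, is_artifact, sub_class (the 6-class substitution label,
    empty for indels). Deamination artifacts have ``true_af_ff == 0`` and
    ``sub_class == "C>T"`` by construction.
    """

    variants: pd.DataFrame
    purity: float
    clonal_af_mode: float
    subclone_fraction: float

    def to_tsv(self, path) -> None:
        self.variants.to_csv(path, sep="\t", index=False)


def _copy_number_at(config: SimulationConfig, chrom: np.ndarray,
                    pos0: np.ndarray) -> np.ndarray:
    cn = np.full(len(chrom), 2.0)
    for seg_chrom, start, end, seg_cn in config.cna_segments:
        mask = (chrom == seg_chrom) & (pos0 >= start) & (pos0 < end)
        cn[mask] = seg_cn
    return cn


def _random_positions(config: SimulationConfig, rng: np.random.Generator,
                      n: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform distinct genomic positions as (chrom array, 0-based pos array)."""
    offsets: list[tuple[str, int, int]] = []
    acc = 0
    for chrom, length in config.chrom_lengths.items():
        offsets.append((chrom, acc, length))
        acc += length
    # rejection-free-ish unique draw; collisions are vanishingly rare for
    # n << genome_size but we top up until exactly n distinct positions
    flat = np.unique(rng.integers(0, config.genome_size, size=n + max(10, n // 10)))
    while len(flat) < n:
        extra = rng.integers(0, config.genome_size, size=n)
        flat = np.unique(np.concatenate([flat, extra]))
    flat = rng.permutation(flat)[:n]
    flat.sort()
    chroms = np.empty(n, dtype=object)
    pos0 = np.empty(n, dtype=np.int64)
    for chrom, start, length in offsets:
        mask = (flat >= start) & (flat < start + length)
        chroms[mask] = chrom
        pos0[mask] = flat[mask] - start
    return chroms, pos0


def simulate_truth(config: SimulationConfig) -> TumorTruthSet:
    """Draw the shared tumor truth set for one FF/FFPE pair.

    Clonal variants (fraction ``1 - subclone_fraction``) have identical true
    AF in both specimens, drawn from a beta peaked at
    ``purity * clonal_af_mode``. Subclonal variants additionally have their
    AF attenuated in one randomly chosen specimen (intratumor/sampling
    heterogeneity). FFPE-only C>T artifacts are appended at a Poisson rate
    of ``deamination_rate`` per Mb with low-AF beta-distributed fractions.
    """
    rng = config.rng(_STREAM_TRUTH)
    n = config.n_variants
    mode = config.purity * config.clonal_af_mode
    kappa = config.clonal_concentration
    a_clonal = 1.0 + mode * kappa
    b_clonal = 1.0 + (1.0 - mode) * kappa

    af = rng.beta(a_clonal, b_clonal, size=n)
    is_sub = rng.random(n) < config.subclone_fraction
    n_sub = int(is_sub.sum())
    af[is_sub] = rng.beta(config.subclone_af_alpha, config.subclone_af_beta,
                          size=n_sub)
    af_ff = af.copy()
    af_ffpe = af.copy()
    # each subclonal variant is attenuated in exactly one specimen
    atten = rng.uniform(0.0, 0.3, size=n_sub)
    in_ff = rng.random(n_sub) < 0.5
    sub_idx = np.flatnonzero(is_sub)
    af_ff[sub_idx[in_ff]] *= atten[in_ff]
    af_ffpe[sub_idx[~in_ff]] *= atten[~in_ff]

    is_indel = rng.random(n) < config.indel_fraction
    classes = rng.choice(SUBSTITUTION_CLASSES, size=n)
    classes[is_indel] = ""

    n_art = rng.poisson(config.deamination_rate * config.genome_size / 1e6)
    n_total = n + int(n_art)
    chroms, pos0 = _random_positions(config, rng, n_total)
    order = rng.permutation(n_total)
    art_slots = order[:n_art] if n_art else np.array([], dtype=int)
    var_slots = order[n_art:]

    chrom_col = np.empty(n_total, dtype=object)
    pos_col = np.empty(n_total, dtype=np.int64)
    ref_col = np.empty(n_total, dtype=object)
    alt_col = np.empty(n_total, dtype=object)
    vclass_col = np.empty(n_total, dtype=object)
    ff_col = np.zeros(n_total)
    ffpe_col = np.zeros(n_total)
    art_col = np.zeros(n_total, dtype=bool)
    class_col = np.empty(n_total, dtype=object)

    rows = np.concatenate([var_slots, art_slots]).astype(int)
    chrom_col[:] = chroms[rows]
    pos_col[:] = pos0[rows] + 1  # to 1-based

    for i in range(n):
        j = i
        if is_indel[i]:
            if rng.random() < 0.5:
                ref_col[j], alt_col[j], vclass_col[j] = "CA", "C", "DEL"
            else:
                ref_col[j], alt_col[j], vclass_col[j] = "C", "CT", "INS"
        else:
            ref, alt = _CLASS_TO_ALLELES[classes[i]]
            ref_col[j], alt_col[j], vclass_col[j] = ref, alt, "SNV"
        class_col[j] = classes[i]
        ff_col[j] = af_ff[i]
        ffpe_col[j] = af_ffpe[i]

    art_af = rng.beta(config.artifact_af_alpha, config.artifact_af_beta,
                      size=n_art)
    for k in range(int(n_art)):
        j = n + k
        ref_col[j], alt_col[j], vclass_col[j] = "C", "T", "SNV"
        class_col[j] = "C>T"
        ff_col[j] = 0.0
        ffpe_col[j] = art_af[k]
        art_col[j] = True

    df = pd.DataFrame({
        "chrom": chrom_col, "pos": pos_col, "ref": ref_col, "alt": alt_col,
        "vclass": vclass_col, "true_af_ff": np.clip(ff_col, 0.0, 1.0),
        "true_af_ffpe": np.clip(ffpe_col, 0.0, 1.0),
        "is_artifact": art_col, "sub_class": class_col,
    }).sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    return TumorTruthSet(variants=df, purity=config.purity,
                         clonal_af_mode=config.clonal_af_mode,
                         subclone_fraction=config.subclone_fraction)


def _draw_depths(rng: np.random.Generator, mean: float, dispersion: float,
                 n: int) -> np.ndarray:
    """Negative-binomial depths with variance = dispersion * mean."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1.0:
        return rng.poisson(mean, size=n)
    p = 1.0 / dispersion
    r = mean * p / (1.0 - p)
    return rng.negative_binomial(r, p, size=n)


def _sample_one_specimen(truth: TumorTruthSet, config: SimulationConfig,
                         rng: np.random.Generator,
                         specimen: str) -> list[VariantRecord]:
    df = truth.variants
    mean = config.depth_ff if specimen == "FF" else config.depth_ffpe
    disp = 1.0 if specimen == "FF" else config.ffpe_dispersion_multiplier
    af = df["true_af_ff" if specimen == "FF" else "true_af_ffpe"].to_numpy()
    depths = _draw_depths(rng, mean, disp, len(df))
    alts = rng.binomial(depths, af)
    called = alts >= config.min_alt_reads
    records = [
        VariantRecord(chrom=str(c), pos=int(p), ref=str(r), alt=str(a),
                      depth=int(d), alt_count=int(k))
        for c, p, r, a, d, k in zip(
            df["chrom"].to_numpy()[called], df["pos"].to_numpy()[called],
            df["ref"].to_numpy()[called], df["alt"].to_numpy()[called],
            depths[called], alts[called])
    ]
    records.sort(key=lambda v: v.key)
    return records


def sample_observed_callsets(
    truth: TumorTruthSet, config: SimulationConfig
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Observe the truth set through binomial read sampling in each specimen.

    Per variant and specimen, site depth is drawn around the specimen mean
    (negative-binomial for FFPE with the configured dispersion) and the alt
    read count is Binomial(depth, true_af). A variant is *called* when its
    alt count reaches ``min_alt_reads``.
    """
    rng = config.rng(_STREAM_CALLS)
    ff = _sample_one_specimen(truth, config, rng, "FF")
    ffpe = _sample_one_specimen(truth, config, rng, "FFPE")
    return ff, ffpe


def replicate_callsets(truth: TumorTruthSet, config: SimulationConfig,
                       specimen: str, n_callers: int) -> list[list[VariantRecord]]:
    """Independent re-observations of one specimen, emulating multiple callers.

    Each replicate redraws depth and alt counts; intersecting the replicates
    mimics the high-confidence multi-caller consensus step.
    """
    rng = config.rng(_STREAM_CALLS)
    return [_sample_one_specimen(truth, config, rng, specimen)
            for _ in range(n_callers)]


def _bin_grid(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    chroms, starts, ends = [], [], []
    for chrom, length in config.chrom_lengths.items():
        edges = np.arange(0, length, config.bin_size)
        chroms.extend([chrom] * len(edges))
        starts.extend(edges.tolist())
        ends.extend(np.minimum(edges + config.bin_size, length).tolist())
    return (np.array(chroms, dtype=object), np.array(starts, dtype=np.int64),
            np.array(ends, dtype=np.int64))


def simulate_coverage(config: SimulationConfig, specimen: str,
                      role: str = "tumor") -> list[CoverageBin]:
    """Per-bin read depth for one specimen.

    Tumor bins scale with local copy number; FFPE bins additionally carry a
    GC-dependent bias (AT-rich bins lose depth, mimicking AT dropout) and
    negative-binomial overdispersion. ``role="normal"`` simulates the
    copy-neutral blood sample at ``depth_normal`` with FF-like uniformity.
    """
    if specimen not in ("FF", "FFPE"):
        raise ValueError("specimen must be 'FF' or 'FFPE'")
    if role not in ("tumor", "normal"):
        raise ValueError("role must be 'tumor' or 'normal'")
    rng = config.rng(_STREAM_COV)
    chroms, starts, ends = _bin_grid(config)
    mid = (starts + ends) // 2
    n = len(chroms)
    gc = np.clip(rng.normal(0.45, 0.08, size=n), 0.2, 0.75)
    if role == "normal":
        mean_depth, disp, cn = config.depth_normal, 1.0, np.full(n, 2.0)
        bias = np.ones(n)
    else:
        cn = _copy_number_at(config, chroms, mid)
        if specimen == "FF":
            mean_depth, disp = config.depth_ff, 1.0
            bias = np.ones(n)
        else:
            mean_depth, disp = config.depth_ffpe, config.ffpe_dispersion_multiplier
            bias = np.exp(config.gc_bias_strength * (gc - 0.45) / 0.45)
            bias = bias / bias.mean()  # preserve the configured mean depth
    means = mean_depth * (cn / 2.0) * bias
    depths = _draw_depths(rng, means, disp, n).astype(float)
    return [CoverageBin(str(c), int(s), int(e), float(d), gc=float(g))
            for c, s, e, d, g in zip(chroms, starts, ends, depths, gc)]


def simulate_cna_tracks(config: SimulationConfig) -> tuple[CnaProfile, CnaProfile]:
    """Per-bin Log2R (and BAF) tracks for the FF and FFPE specimens.

    Log2R per bin is log2(copy_number/2) plus Gaussian noise; the FFPE track
    adds a sinusoidal wave of configured amplitude and period, emulating the
    low-frequency coverage oscillation seen in degraded libraries. BAF is
    the major-allele fraction implied by integer copy number, noised.
    """
    rng = config.rng(_STREAM_CNA)
    chroms, starts, ends = _bin_grid(config)
    mid = (starts + ends) / 2.0
    cn = _copy_number_at(config, chroms, mid.astype(np.int64))
    # blend toward copy-neutral for impure tumors
    eff = config.purity * cn + (1.0 - config.purity) * 2.0
    base = np.log2(eff / 2.0)

    baf_true = np.where(cn > 0, np.maximum(cn - 1, 1) / np.maximum(cn, 1), 0.5)
    baf_true = np.where(cn == 2, 0.5, baf_true)

    log2r_ff = base + rng.normal(0.0, config.log2r_noise_sd_ff, size=len(cn))
    # cumulative genome coordinate so the wave is continuous across chromosomes
    acc, genome_pos = 0, np.zeros(len(cn))
    for chrom, length in config.chrom_lengths.items():
        mask = chroms == chrom
        genome_pos[mask] = mid[mask] + acc
        acc += length
    phase = rng.uniform(0.0, 2.0 * np.pi)
    wave = config.wave_amplitude * np.sin(
        2.0 * np.pi * genome_pos / config.wave_period + phase)
    log2r_ffpe = (base + wave
                  + rng.normal(0.0, config.log2r_noise_sd_ffpe, size=len(cn)))

    baf_ff = np.clip(baf_true + rng.normal(0, 0.03, size=len(cn)), 0, 1)
    baf_ffpe = np.clip(baf_true + rng.normal(0, 0.06, size=len(cn)), 0, 1)

    def _profile(log2r, baf, label):
        return CnaProfile(
            bins=pd.DataFrame({
                "chrom": chroms, "start": starts, "end": ends,
                "log2r": log2r, "baf": baf,
            }),
            sample_label=label,
        )

    return _profile(log2r_ff, baf_ff, "FF"), _profile(log2r_ffpe, baf_ffpe, "FFPE")
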