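# Methods

This note documents the models behind `ffconcord`: what each statistic
assumes, what the synthetic paired-tumor generator does and does not
emulate, and the numerical conventions chosen where several were defensible.

## Variant identity and normalization

All comparisons use the exact key (chrom, pos, ref, alt) after
normalization: shared suffix then shared prefix of the allele pair is
trimmed (position advanced per trimmed prefix base), which left-aligns and
minimalizes indels using allele strings alone. No reference FASTA is
consulted and no fuzzy or windowed matching is attempted — two call sets
agree on a variant only if they spell the same normalized allele at the
same coordinate. Chromosome dialects are harmonized at I/O time (default:
strip a leading `chr`; a user alias map overrides). VCF positions are
1-based; BED/bedGraph intervals are 0-based half-open, so a variant at
1-based position *p* lies in interval \[s, e) iff s < p ≤ e. Allelic
fraction is always recomputed as alt_count/depth from the FORMAT AD/DP
fields rather than trusted from caller-specific INFO annotations, so AFs
are comparable across callers; records lacking depth evidence keep
`depth=None` and are flagged rather than dropped.

## Concordance statistics

The tri-set partition treats calls as presence/absence with evidence
attached. Agreement uses the union as denominator (the three pie sections
sum to 100 %); sensitivity and PPV use the fresh-frozen set as reference.
The two families are exposed separately and never conflated. A partition
of two empty sets raises rather than reporting 0 or 1: agreement is
undefined there, and silently choosing a value would poison sweeps.
Multi-caller consensus is the exact key intersection; evidence fields of
the first listed callset are kept.

## The binomial power model

Detection power is P(X ≥ k) with X ~ Binomial(depth, AF), the probability
that a true variant yields at least k supporting reads; `min_detectable_af`
inverts it on a 10⁻⁴ AF grid. The power filter keeps a variant key iff
depth > 70 in **both** specimens and AF > 0.067 in **at least one**
(strict inequalities, as the thresholds are stated for the emulated
design). The defaults k = 3 and target power 0.9 are this package's
reconstruction of a filter whose exact parameters were not published with
the design it emulates; both are configurable. At 70× and k = 3 the
smallest AF with 90 % power is 0.0743, so the 0.067 threshold corresponds
to slightly under 90 % power — consistent with, not derivable from, the
stated operating point. Depth in the specimen where a variant was *not*
called is resolved from that specimen's coverage track at the variant
position (nearest containing bin). This is an approximation — bin-mean
depth stands in for site depth — documented rather than hidden, because
callers emit no records at non-called sites.

## Coverage metrics

Threshold fractions are base-weighted (bins count by width). Uniformity is
the population standard deviation of window mean depths after aggregating
bins into fixed windows (default 100 kb) by base-weighted overlap; windows
truncated at chromosome ends keep base weighting. Population rather than
sample SD is used (the convention is not standardized; the difference is
negligible at genome scale). Dropout follows the Picard-style definition:
bins are classed by integer GC percentage; with w the bin fraction and r
the depth-mass fraction of a class, AT dropout is 100·Σ_{GC<50} max(0, w−r)
and GC dropout the same over GC>50. Both are invariant to uniform depth
rescaling and zero for GC-neutral coverage.

## Copy-number concordance

Log2R per bin is log2((tᵢ/T)/(nᵢ/N)) with T, N the track totals —
library-size normalization makes the profile invariant to sequencing
effort. Bins with normal depth below a floor (default 10×) are masked NaN,
not dropped, so grids stay aligned; a bin masked in either profile is
excluded from correlation. Concordance is the Spearman rank correlation of
per-bin Log2R over shared usable bins (mid-ranks for ties, ≥30 bins
required), computed on raw bins rather than segment means: no segmentation
is attempted, because the emulated workflow's CNA calls were manually
curated and segmentation choices would dominate the statistic. One
consequence worth knowing: for a genome of well-separated copy-number
levels with group fractions w_g, within-group ranks are noise, so the
correlation is ceiling-limited at roughly 1 − Σ w_g³ even for noiseless
tracks. The default synthetic genome (70 % copy-neutral) therefore tops
out near 0.66 — the *differences* between conditions, not the absolute
value, carry the signal.

## Mutation spectra and the artifact-burden estimator

Single-base substitutions collapse onto the six pyrimidine-context classes
(purine-strand events mapped through reverse complement). Spectrum
comparison reports per-class fraction differences and the Pearson
chi-square of the 2×6 count table (df = 5, no continuity correction).

Deamination injects FFPE-only low-AF C>T. Its burden is estimated from a
partition as the low-AF C>T count in FFPE-unique calls minus the same
count in FF-unique calls: genuine subclonal divergence contributes low-AF
C>T to both unique sets roughly symmetrically, so the subtraction cancels
the heterogeneity background. Two refinements make the estimate
quantitative rather than a lower bound: each called variant is weighted by
the inverse of its binomial detection probability at its observed depth
and AF (a Horvitz–Thompson correction for artifacts present in the DNA but
missed by sampling), and the AF window extends to 0.15 (default) so that
sampling noise around a true AF near 0.06 does not push calls out of the
window. A raw unweighted count at AF < 0.1 targets only the *called*
artifact subset and under-recovers by ~25–50 % under the default
conditions; the corrected estimator recovers the injected rate within
~±10–15 %. Residual bias sources: the plug-in AF in the weight is
selection-biased upward near the read-count threshold, and the
FF/FFPE depth asymmetry makes the background subtraction slightly
conservative.

## The synthetic paired-tumor generator

The generator emulates two specimens cut from adjacent regions of one
tumor, sequenced against a matched blood normal. Its defaults are the
study conditions of the emulated design:

| parameter | default | meaning |
| --- | --- | --- |
| depth_ff / depth_ffpe / depth_normal | 93× / 77× / 30× | measured specimen means around a 70× tumor target |
| purity, clonal_af_mode | 0.8, 0.4 | clonal AF peak at purity·0.4 ≈ 0.32 |
| subclone_fraction | 0.3 | fraction of variants attenuated in one specimen |
| deamination_rate | 1 /Mb | FFPE-only C>T artifacts (a demonstration scale; real burdens vary widely) |
| artifact AF | Beta(10, 150) | peaked near 0.06: low-level but mostly above the 3-read detection floor |
| ffpe_dispersion_multiplier | 3 | coverage variance inflation, inside the reported 1.1–5.8× SD range |
| gc_bias_strength | 1 | FFPE AT-dropout emulation |
| wave_amplitude / period | 0.3 / 5 Mb | low-frequency Log2R oscillation of degraded libraries |
| n_variants, genome | 2000 over 200 Mb | scaled-down genome: two chromosomes, three CNA segments |

Truth AFs are a two-component mixture: clonal Beta peaked at
purity·clonal_af_mode, subclonal Beta(2, 18); each subclonal variant is
attenuated by Uniform(0, 0.3) in one randomly chosen specimen (intratumor
plus sampling heterogeneity). Observation draws site depth around the
specimen mean — Poisson for FF, negative-binomial with variance =
dispersion·mean for FFPE — then alt reads ~ Binomial(depth, true AF); a
variant is called at ≥3 alt reads, a single-threshold stand-in for the
caller ensemble (independent re-observations emulate multiple callers for
intersection tests). Because FF depth is Poisson-distributed, the marginal
alt count is Poisson(mean·AF), which gives the closed-form call
probability the tests check against. Coverage bins draw from the same
depth law scaled by local copy number, with FFPE bins additionally biased
by exp(strength·(GC−0.45)/0.45), mean-normalized so the configured depth
is preserved. Log2R tracks are log2(effective copy / 2) — effective copy
blends toward 2 with decreasing purity — plus Gaussian noise, and for FFPE
a phase-random sinusoid continuous across the genome. BAF is the
major-allele fraction implied by integer copy number, noised.

Every draw derives from one integer seed through per-stage RNG streams;
identical configs are byte-reproducible.

**What the generator does not model:** read-level data (no FASTQ/BAM, no
fragment-length or mappability structure), sequence context beyond the
six-class label, germline contamination, caller-specific error modes, and
segmentation noise. Passing tests therefore demonstrate that the
*analysis* behaves correctly under the stated statistical structure — they
do not certify performance on real FFPE libraries, whose artifact spectra
and coverage pathologies are richer.

## Problem sizes and determinism

Tests and the acceptance script run the generator at its defaults (2000
truth variants over a 200-Mb two-chromosome genome, 2000 coverage bins) or
on a 30-Mb single-chromosome variant for replicated checks (100 seeded
replicates for directional claims: AF-sweep monotonicity, power-filter
gain, SD inflation, wave degradation). Monotonicity of the AF sweep is
assessed after an isotonic (pool-adjacent-violators) fit: the sequence
counts as monotone when residuals stay within 0.02 and the fitted curve
ends above its start. Coverage QC comparisons use a copy-neutral genome so
window SD measures library dispersion rather than tumor structure. All
stochastic tests fix seeds; hypothesis-based property tests run
derandomized.

## Known limitations

- Cross-sample depth for uncalled sites comes from binned coverage, not
  site pileups; near copy-number breakpoints the bin mean can misstate the
  local depth.
- `compute_log2r` requires identical bin grids and does not re-bin; callers
  of mismatched tracks must aggregate first.
- The report table matches CNAs at (gene, direction) granularity;
  breakpoint-level CNA concordance is out of scope, as are segmentation,
  purity/ploidy correction and LOH calling from BAF (BAF is emitted but
  not analyzed).
- Tier rules are taken from a user-supplied table; the bundled demo rules
  are synthetic and carry no clinical meaning.
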