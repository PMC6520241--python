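"""Substitution-class spectra and deamination diagnostics.

Single-base substitutions are collapsed to the six pyrimidine-context
classes (C>A, C>G, C>T, T>A, T>C, T>G): a substitution observed on the
purine strand is mapped through reverse complement (G>A is counted as C>T,
and so on), the standard convention in mutational-spectrum analysis.

FFPE fixation deaminates cytosine, which sequencing reads as C>T / G>A at
low allelic fraction, so an excess of low-AF C>T among FFPE-unique calls is
the signature of fixation artifacts rather than true somatic divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import VariantRecord

__all__ = [
    "SUBSTITUTION_CLASSES",
    "SpectrumSummary",
    "substitution_class",
    "spectrum",
    "compare_spectra",
    "estimate_artifact_excess",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_AF_BIN_WIDTH = 0.02


def substitution_class(ref: str, alt: str) -> str:
    """Collapse a single-base substitution onto its pyrimidine-context class."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"not a variant: {ref}>{alt}")
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT alleles: {ref}>{alt}")
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class SpectrumSummary:
    """Six-class substitution counts plus the AF histogram of the SNVs."""

    counts: dict[str, int]
    n_snv: int
    n_skipped: int                      # non-SNV records, not classified
    ct_fraction: float | None           # None when no SNVs (undefined, flagged)
    af_bin_edges: np.ndarray
    af_histogram: np.ndarray
    n_af_unknown: int = 0

    def fractions(self) -> dict[str, float]:
        if self.n_snv == 0:
            return {c: float("nan") for c in SUBSTITUTION_CLASSES}
        return {c: self.counts[c] / self.n_snv for c in SUBSTITUTION_CLASSES}


def spectrum(variants: Sequence[VariantRecord],
             af_bin_width: float = DEFAULT_AF_BIN_WIDTH) -> SpectrumSummary:
    """Class counts, C>T fraction and AF histogram of a variant subset.

    Only SNVs are classified; other variant classes are skipped and counted
    in ``n_skipped``. The C>T fraction is ``None`` for an empty SNV set.
    """
    if not 0.0 < af_bin_width <= 1.0:
        raise ValueError("af_bin_width must be in (0,1]")
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    afs: list[float] = []
    n_skipped = n_af_unknown = 0
    for v in variants:
        if v.vclass != "SNV":
            n_skipped += 1
            continue
        counts[substitution_class(v.ref, v.alt)] += 1
        if v.af is None:
            n_af_unknown += 1
        else:
            afs.append(v.af)
    n_snv = sum(counts.values())
    n_bins = int(np.ceil(1.0 / af_bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * af_bin_width, 1.0)
    hist, _ = np.histogram(afs, bins=edges)
    return SpectrumSummary(
        counts=counts, n_snv=n_snv, n_skipped=n_skipped,
        ct_fraction=(counts["C>T"] / n_snv) if n_snv else None,
        af_bin_edges=edges, af_histogram=hist, n_af_unknown=n_af_unknown,
    )


def compare_spectra(a: SpectrumSummary, b: SpectrumSummary) -> dict:
    """Per-class fraction differences and a chi-square test on the 2x6 table.

    The statistic is the Pearson chi-square of the 2x6 contingency table of
    class counts (df = 5, no continuity correction). Identical spectra give
    zero differences and a zero statistic.
    """
    fa, fb = a.fractions(), b.fractions()
    diffs = {c: fa[c] - fb[c] for c in SUBSTITUTION_CLASSES}
    table = np.array([[a.counts[c] for c in SUBSTITUTION_CLASSES],
                      [b.counts[c] for c in SUBSTITUTION_CLASSES]], dtype=float)
    # drop all-zero classes: they contribute nothing and break the test
    nonzero = table.sum(axis=0) > 0
    if a.n_snv == 0 or b.n_snv == 0:
        chi2, pval, dof = float("nan"), float("nan"), 0
    elif np.array_equal(table[0], table[1]):
        chi2, pval, dof = 0.0, 1.0, int(nonzero.sum()) - 1
    else:
        chi2, pval, dof, _ = stats.chi2_contingency(table[:, nonzero],
                                                    correction=False)
    return {
        "fractions_a": fa,
        "fractions_b": fb,
        "differences": diffs,
        "chi2": float(chi2),
        "p_value": float(pval),
        "dof": int(dof),
    }


def _low_af_ct(variants: Sequence[VariantRecord], af_max: float,
               min_alt_reads: int, power_corrected: bool) -> float:
    total = 0.0
    for v in variants:
        if v.vclass != "SNV" or v.af is None or v.af >= af_max:
            continue
        if substitution_class(v.ref, v.alt) != "C>T":
            continue
        if power_corrected:
            # Horvitz-Thompson style: weight each called variant by the
            # inverse probability that a variant at its (depth, AF) would
            # have produced at least min_alt_reads supporting reads
            p = float(stats.binom.sf(min_alt_reads - 1, v.depth, v.af)) \
                if min_alt_reads > 0 else 1.0
            total += 1.0 / max(p, 1e-6)
        else:
            total += 1.0
    return total


def estimate_artifact_excess(ffpe_unique: Sequence[VariantRecord],
                             ff_unique: Sequence[VariantRecord],
                             af_max: float = 0.15,
                             min_alt_reads: int = 3,
                             power_corrected: bool = True) -> float:
    """Estimate the FFPE deamination artifact burden from a tri-set partition.

    Deamination creates FFPE-only low-AF C>T calls, but low-AF C>T calls
    also arise from genuine subclonal divergence - which affects both
    specimens symmetrically. The excess of low-AF (< ``af_max``) C>T counts
    in the FFPE-unique set over the FF-unique set therefore estimates the
    artifact burden with the heterogeneity background subtracted.

    With ``power_corrected`` each call is weighted by the inverse of its
    binomial detection probability at its observed depth and AF, correcting
    for artifacts present in the DNA but missed by read sampling; the
    estimate then targets the total artifact count rather than the called
    subset.
    """
    return (_low_af_ct(ffpe_unique, af_max, min_alt_reads, power_corrected)
            - _low_af_ct(ff_unique, af_max, min_alt_reads, power_corrected))
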