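"""Expected log-ratios and allele fractions for an admixed tumor specimen.

A cancer specimen is modeled as a fraction ``p`` of tumor cells mixed with
``1 - p`` diploid normal cells.  A genomic segment at integer copy number
``C`` in the tumor contributes ``p*C + 2*(1 - p)`` chromosome copies per
cell on average, against a genome-wide baseline of ``p*psi + 2*(1 - p)``
where ``psi`` is the tumor ploidy (the length-weighted mean copy number).
Coverage log-ratios, heterozygous-SNP minor allele fractions, and variant
allele fractions under the germline and somatic hypotheses all follow from
these two mixture terms.

All functions accept scalars or numpy arrays and broadcast.  The degenerate
point ``p == 1, C == 0`` (a fully pure tumor with a homozygous deletion
leaves no DNA at all) yields ``-inf`` log-ratios and ``nan`` fractions,
which callers treat as an "undefined expectations" sentinel.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "tumor_mix_copies",
    "expected_log_ratio",
    "expected_maf",
    "expected_af_germline",
    "expected_af_somatic",
    "compute_ploidy",
]


def tumor_mix_copies(p, C):
    """Average chromosome copies per cell, ``p*C + 2*(1 - p)``."""
    p = np.asarray(p, dtype=float)
    C = np.asarray(C, dtype=float)
    return p * C + 2.0 * (1.0 - p)


def expected_log_ratio(p, C, ploidy):
    """Expected coverage log2-ratio of a segment at copy number ``C``.

    ``log2[(p*C + 2(1-p)) / (p*psi + 2(1-p))]`` — the segment's mixture
    copy count against the ploidy-normalized baseline.  Returns ``-inf``
    where ``p == 1`` and ``C == 0``.
    """
    num = tumor_mix_copies(p, C)
    den = tumor_mix_copies(p, ploidy)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(num) - np.log2(den)
    return out


def expected_maf(p, C, M):
    """Expected minor allele fraction of het SNPs in a (C, M) segment.

    ``(p*M + 1-p) / (p*C + 2(1-p))``: the tumor contributes ``M`` minor
    copies, the normal exactly one of each parental allele.  Undefined
    (``nan``) at ``p == 1, C == 0``.
    """
    p = np.asarray(p, dtype=float)
    M = np.asarray(M, dtype=float)
    den = tumor_mix_copies(p, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (p * M + (1.0 - p)) / den
    return out


def expected_af_germline(p, C, V):
    """Expected allele fraction of a germline variant carried on ``V`` of
    the ``C`` tumor copies (the het normal always contributes one copy):
    ``(p*V + 1-p) / (p*C + 2(1-p))``.
    """
    p = np.asarray(p, dtype=float)
    V = np.asarray(V, dtype=float)
    den = tumor_mix_copies(p, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (p * V + (1.0 - p)) / den
    return out


def expected_af_somatic(p, C, V):
    """Expected allele fraction of a clonal somatic mutation on ``V`` of
    the ``C`` tumor copies (absent from the normal): ``p*V / (p*C + 2(1-p))``.
    """
    p = np.asarray(p, dtype=float)
    V = np.asarray(V, dtype=float)
    den = tumor_mix_copies(p, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (p * V) / den
    return out


def compute_ploidy(lengths, copy_numbers):
    """Tumor ploidy: the length-weighted mean copy number, Σ l_i C_i / Σ l_i."""
    lengths = np.asarray(lengths, dtype=float)
    copy_numbers = np.asarray(copy_numbers, dtype=float)
    if lengths.size == 0:
        raise ValueError("cannot compute ploidy of an empty segment list")
    if np.any(lengths <= 0):
        raise ValueError("segment lengths must be positive")
    if lengths.shape != copy_numbers.shape:
        raise ValueError("lengths and copy_numbers must have the same shape")
    return float(np.sum(lengths * copy_numbers) / np.sum(lengths))
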