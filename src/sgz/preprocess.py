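"""Raw coverage and SNP counts -> log-ratio and minor-allele-fraction profiles.

The copy-number model consumes two genome-wide profiles: the
median-normalized log2 tumor/normal coverage ratio per bin (GC-corrected
by Lowess regression) and the folded minor allele fraction of SNPs judged
heterozygous.  Heterozygosity is decided tumor-only from an allele-fraction
window, wide enough that het SNPs displaced by LOH at moderate purity are
retained; the window is a documented sensitivity knob.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LogRatioProfile",
    "MafProfile",
    "compute_log_ratio",
    "gc_correct",
    "select_het_snps",
]


@dataclass
class LogRatioProfile:
    """Per-bin log2 tumor/normal coverage ratios, median-centered.

    ``bins`` columns: chrom, start, end, gc, log_ratio.
    """

    bins: pd.DataFrame
    n_dropped: int = 0
    median_normalized: bool = True
    gc_corrected: bool = False


@dataclass
class MafProfile:
    """Per-SNP allele fractions with a heterozygosity flag.

    ``snps`` columns: chrom, pos, depth, alt_fraction, minor_fraction,
    is_het.  All depth-passing SNPs are retained; segment-level MAF
    statistics downstream use only the ``is_het`` rows, while the
    near-purity heuristic inspects the full het-band occupancy.
    """

    snps: pd.DataFrame
    het_window: tuple[float, float] = (0.10, 0.90)
    min_depth: int = 20

    @property
    def het(self) -> pd.DataFrame:
        return self.snps[self.snps["is_het"]]


def compute_log_ratio(bins: pd.DataFrame) -> LogRatioProfile:
    """log2(tumor/normal) per bin, median-centered.

    Bins with zero tumor or zero normal depth are unusable (a
    process-matched-normal failure indicates an unreliable bin) and are
    dropped and counted rather than imputed.
    """
    required = {"chrom", "start", "end", "tumor_depth", "normal_depth"}
    missing = required - set(bins.columns)
    if missing:
        raise ValueError(f"coverage table lacks columns: {sorted(missing)}")
    usable = (bins["normal_depth"] > 0) & (bins["tumor_depth"] > 0)
    n_dropped = int((~usable).sum())
    kept = bins.loc[usable].reset_index(drop=True).copy()
    if kept.empty:
        raise ValueError("no usable coverage: every bin has zero tumor or normal depth")
    lr = np.log2(kept["tumor_depth"].to_numpy(float) / kept["normal_depth"].to_numpy(float))
    lr = lr - np.median(lr)
    kept["log_ratio"] = lr
    if "gc" not in kept.columns:
        kept["gc"] = np.nan
    cols = ["chrom", "start", "end", "gc", "log_ratio"]
    return LogRatioProfile(bins=kept[cols], n_dropped=n_dropped)


def gc_correct(
    profile: LogRatioProfile,
    frac: float = 0.3,
    iterations: int = 1,
    min_bins: int = 30,
) -> LogRatioProfile:
    """Remove the GC-content coverage trend by Lowess regression.

    The Lowess-smoothed trend of log-ratio against GC fraction is
    subtracted and the profile re-median-centered.  With fewer than
    ``min_bins`` bins there is too little support for a smoother and the
    profile is returned unchanged with a warning.
    """
    bins = profile.bins
    gc = bins["gc"].to_numpy(float)
    if not np.all((gc >= 0) & (gc <= 1)):
        raise ValueError("gc fractions must lie in [0, 1]")
    if len(bins) < min_bins:
        warnings.warn(
            f"gc_correct skipped: only {len(bins)} bins (< {min_bins})",
            stacklevel=2,
        )
        return LogRatioProfile(
            bins=bins.copy(), n_dropped=profile.n_dropped, gc_corrected=False
        )
    lr = bins["log_ratio"].to_numpy(float)
    if np.ptp(gc) == 0.0:
        # constant GC: the trend is a constant shift, removed by re-centering
        trend = np.full_like(lr, lr.mean())
    else:
        fitted = sm.nonparametric.lowess(
            lr, gc, frac=frac, it=iterations, return_sorted=True
        )
        trend = np.interp(gc, fitted[:, 0], fitted[:, 1])
    corrected = lr - trend
    corrected = corrected - np.median(corrected)
    out = bins.copy()
    out["log_ratio"] = corrected
    return LogRatioProfile(bins=out, n_dropped=profile.n_dropped, gc_corrected=True)


def select_het_snps(
    snps: pd.DataFrame,
    min_depth: int = 20,
    het_window: tuple[float, float] = (0.10, 0.90),
) -> MafProfile:
    """Flag heterozygous SNPs and fold their allele fractions.

    SNPs below ``min_depth`` are removed.  A SNP whose unfolded alt
    fraction lies inside ``het_window`` is flagged heterozygous; its minor
    fraction is ``min(f, 1 - f)``.  Non-het SNPs remain in the profile
    (flagged False) for the high-purity occupancy check.
    """
    required = {"chrom", "pos", "depth", "alt_depth"}
    missing = required - set(snps.columns)
    if missing:
        raise ValueError(f"SNP table lacks columns: {sorted(missing)}")
    kept = snps.loc[snps["depth"] >= min_depth].reset_index(drop=True).copy()
    depth = kept["depth"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, kept["alt_depth"].to_numpy(float) / depth, np.nan)
    lo, hi = het_window
    kept["alt_fraction"] = af
    kept["minor_fraction"] = np.minimum(af, 1.0 - af)
    kept["is_het"] = (af >= lo) & (af <= hi)
    cols = ["chrom", "pos", "depth", "alt_fraction", "minor_fraction", "is_het"]
    return MafProfile(snps=kept[cols], het_window=het_window, min_depth=min_depth)
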