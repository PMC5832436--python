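"""Circular binary segmentation of the log-ratio profile.

The genome is partitioned, chromosome by chromosome, into segments of
homogeneous coverage log-ratio by the canonical recursive CBS scheme: at
each step the arc of bins maximizing the mean-shift statistic against its
complement is found; the split is accepted when its permutation p-value
falls below ``alpha``, and recursion continues until no significant split
remains or segments reach the minimum size.  Segmentation runs on the
log-ratio data only; SNP minor allele fractions are attached to the
resulting segments afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .preprocess import LogRatioProfile, MafProfile

__all__ = [
    "Segment",
    "CBSSegmenter",
    "cbs_segment",
    "summarize_segments",
]

SD_LR_FLOOR = 0.05  # log2 units; prevents zero-variance likelihood collapse
SD_MAF_FLOOR = 0.02


@dataclass
class Segment:
    """A contiguous run of bins with homogeneous copy number signal.

    ``length`` is the bin count l_i (proxy for genomic length); ``maf``
    holds the member het-SNP minor fractions.  ``maf_mean``/``sd_maf`` are
    NaN for SNP-less segments, whose MAF likelihood terms are skipped
    downstream.
    """

    chrom: str
    start: int
    end: int
    n_bins: int
    median_lr: float
    sd_lr: float
    maf: np.ndarray = field(default_factory=lambda: np.empty(0))
    maf_mean: float = float("nan")
    sd_maf: float = float("nan")
    n_snps: int = 0

    @property
    def length(self) -> int:
        return self.n_bins


# ---------------------------------------------------------------------------
# CBS core


def _valid_arcs(n: int, min_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) arc endpoints whose split leaves every piece >= min_bins.

    An arc (i, j] against its complement yields breakpoints at i and j;
    pieces of length i, j-i and n-j must each be empty or >= min_bins.
    """
    I, J = [], []
    for i in range(0, n - min_bins + 1):
        if i != 0 and i < min_bins:
            continue
        j_lo = i + min_bins
        for j in range(j_lo, n + 1):
            if i == 0 and j == n:
                continue  # no split at all
            tail = n - j
            if tail != 0 and tail < min_bins:
                continue
            I.append(i)
            J.append(j)
    return np.asarray(I, dtype=np.intp), np.asarray(J, dtype=np.intp)


def _max_arc_stat(
    x: np.ndarray, I: np.ndarray, J: np.ndarray
) -> tuple[int, int, float]:
    """Arc maximizing |mean(arc) - mean(complement)| / sqrt(1/k + 1/(n-k))."""
    n = x.size
    c = np.concatenate(([0.0], np.cumsum(x)))
    total = c[-1]
    k = (J - I).astype(float)
    sa = c[J] - c[I]
    t = np.abs(sa / k - (total - sa) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
    a = int(np.argmax(t))
    return int(I[a]), int(J[a]), float(t[a])


def _perm_significant(
    x: np.ndarray,
    t_obs: float,
    I: np.ndarray,
    J: np.ndarray,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> bool:
    """Permutation test of the max arc statistic, with early stopping once
    the exceedance count rules out p < alpha."""
    n = x.size
    k = (J - I).astype(float)
    scale = np.sqrt(1.0 / k + 1.0 / (n - k))
    stop_count = math.ceil(alpha * n_perm)
    batch = max(1, int(5_000_000 // max(I.size, 1)))
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        xp = rng.permuted(np.broadcast_to(x, (b, n)).copy(), axis=1)
        c = np.concatenate((np.zeros((b, 1)), np.cumsum(xp, axis=1)), axis=1)
        total = c[:, -1:]
        sa = c[:, J] - c[:, I]
        t = np.abs(sa / k - (total - sa) / (n - k)) / scale
        exceed += int((t.max(axis=1) >= t_obs - 1e-12).sum())
        done += b
        if exceed > stop_count:
            return False
    p = (exceed + 1) / (done + 1)
    return p < alpha


def _segment_array(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    min_bins: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Recursive CBS over one chromosome's bin values; returns half-open
    bin-index intervals."""

    def rec(lo: int, hi: int) -> list[tuple[int, int]]:
        seg = x[lo:hi]
        n = seg.size
        I, J = _valid_arcs(n, min_bins)
        if I.size == 0:
            return [(lo, hi)]
        i, j, t = _max_arc_stat(seg, I, J)
        if t <= 0.0 or np.ptp(seg) == 0.0:
            return [(lo, hi)]
        if not _perm_significant(seg, t, I, J, alpha, n_perm, rng):
            return [(lo, hi)]
        cuts = sorted({i, j} - {0, n})
        edges = [0] + cuts + [n]
        out: list[tuple[int, int]] = []
        for a, b in zip(edges[:-1], edges[1:]):
            out.extend(rec(lo + a, lo + b))
        return out

    return rec(0, x.size)


def cbs_segment(
    profile: LogRatioProfile,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_bins: int = 10,
    random_state: int | None = None,
) -> list[tuple[str, int, int]]:
    """Segment the genome; returns (chrom, lo, hi) half-open bin-index
    ranges, indices local to each chromosome's bin order."""
    rng = np.random.default_rng(random_state)
    out: list[tuple[str, int, int]] = []
    for chrom, sub in profile.bins.groupby("chrom", sort=False):
        x = sub["log_ratio"].to_numpy(float)
        for lo, hi in _segment_array(x, alpha, n_perm, min_bins, rng):
            out.append((str(chrom), lo, hi))
    return out


def summarize_segments(
    profile: LogRatioProfile,
    boundaries: list[tuple[str, int, int]],
    maf_profile: MafProfile | None = None,
    sd_lr_floor: float = SD_LR_FLOOR,
    sd_maf_floor: float = SD_MAF_FLOOR,
) -> list[Segment]:
    """Attach per-segment summary statistics.

    Each segment carries its median log-ratio, the SD of the log-ratio
    data within it, its het SNPs' minor fractions and their SD.  SDs are
    floored so tiny segments cannot collapse a Gaussian likelihood.
    """
    segments: list[Segment] = []
    by_chrom = {str(c): sub.reset_index(drop=True) for c, sub in profile.bins.groupby("chrom", sort=False)}
    het = maf_profile.het if maf_profile is not None else None
    for chrom, lo, hi in boundaries:
        sub = by_chrom[chrom]
        piece = sub.iloc[lo:hi]
        lr = piece["log_ratio"].to_numpy(float)
        start = int(piece["start"].iloc[0])
        end = int(piece["end"].iloc[-1])
        sd = float(np.std(lr, ddof=1)) if lr.size > 1 else 0.0
        seg = Segment(
            chrom=chrom,
            start=start,
            end=end,
            n_bins=int(lr.size),
            median_lr=float(np.median(lr)),
            sd_lr=max(sd, sd_lr_floor),
        )
        if het is not None:
            mask = (
                (het["chrom"] == chrom)
                & (het["pos"] >= start)
                & (het["pos"] < end)
            )
            maf = het.loc[mask, "minor_fraction"].to_numpy(float)
            seg.maf = maf
            seg.n_snps = int(maf.size)
            if maf.size > 0:
                seg.maf_mean = float(np.mean(maf))
                sdf = float(np.std(maf, ddof=1)) if maf.size > 1 else 0.0
                seg.sd_maf = max(sdf, sd_maf_floor)
        segments.append(seg)
    return segments


class CBSSegmenter(BaseEstimator):
    """Circular-binary-segmentation estimator.

    Parameters
    ----------
    alpha : permutation p-value threshold for accepting a split.
    n_perm : permutations per split test (seeded).
    min_bins : minimum bins per resulting segment.
    random_state : seed for the permutation RNG stream.

    Attributes (after ``fit``)
    --------------------------
    boundaries_ : list of (chrom, lo, hi) bin-index ranges.
    segments_ : list of :class:`Segment` with summary statistics.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        n_perm: int = 1000,
        min_bins: int = 10,
        sd_lr_floor: float = SD_LR_FLOOR,
        sd_maf_floor: float = SD_MAF_FLOOR,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.n_perm = n_perm
        self.min_bins = min_bins
        self.sd_lr_floor = sd_lr_floor
        self.sd_maf_floor = sd_maf_floor
        self.random_state = random_state

    def fit(self, X: LogRatioProfile, maf_profile: MafProfile | None = None):
        if not isinstance(X, LogRatioProfile):
            raise TypeError("CBSSegmenter.fit expects a LogRatioProfile")
        if X.bins.empty:
            raise ValueError("empty log-ratio profile")
        self.boundaries_ = cbs_segment(
            X,
            alpha=self.alpha,
            n_perm=self.n_perm,
            min_bins=self.min_bins,
            random_state=self.random_state,
        )
        self.segments_ = summarize_segments(
            X,
            self.boundaries_,
            maf_profile,
            sd_lr_floor=self.sd_lr_floor,
            sd_maf_floor=self.sd_maf_floor,
        )
        self.n_segments_ = len(self.segments_)
        return self

    def fit_predict(self, X: LogRatioProfile, maf_profile: MafProfile | None = None):
        return self.fit(X, maf_profile).segments_


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    """SEG-like table of segment summaries."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_bins": s.n_bins,
                "median_lr": s.median_lr,
                "sd_lr": s.sd_lr,
                "n_snps": s.n_snps,
                "maf_mean": s.maf_mean,
                "sd_maf": s.sd_maf,
            }
            for s in segments
        ]
    )


def segments_from_frame(df: pd.DataFrame) -> list[Segment]:
    out = []
    for row in df.itertuples():
        out.append(
            Segment(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                n_bins=int(row.n_bins),
                median_lr=float(row.median_lr),
                sd_lr=float(row.sd_lr),
                n_snps=int(row.n_snps),
                maf_mean=float(row.maf_mean),
                sd_maf=float(row.sd_maf),
            )
        )
    return out
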