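"""Static genome-wide log-ratio / MAF overview figure."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cnmodel import CopyNumberModel
from .preprocess import LogRatioProfile, MafProfile
from .segmentation import Segment


def plot_genome_profile(
    profile: LogRatioProfile,
    maf: MafProfile | None = None,
    segments: list[Segment] | None = None,
    model: CopyNumberModel | None = None,
    path: str | None = None,
):
    """Two-panel genome overview: per-bin log-ratios with fitted segment
    levels on top, het-SNP minor allele fractions below."""
    bins = profile.bins.reset_index(drop=True)
    chroms = list(dict.fromkeys(bins["chrom"]))
    offsets = {}
    x0 = 0
    for c in chroms:
        offsets[c] = x0
        x0 += (bins["chrom"] == c).sum()
    x = bins.groupby("chrom", sort=False).cumcount() + bins["chrom"].map(offsets)

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(11, 5), sharex=True)
    ax1.plot(x, bins["log_ratio"], ".", ms=2, color="0.6")
    if segments is not None:
        # cumulative bin offset per segment, in genome order
        pos = 0
        for i, seg in enumerate(segments):
            lo, hi = pos, pos + seg.n_bins
            pos = hi
            ax1.hlines(seg.median_lr, lo, hi, color="tab:blue", lw=2)
            if model is not None:
                ax1.hlines(
                    float(model.expected_lr()[i]), lo, hi, color="tab:red", lw=1,
                    linestyles="--",
                )
    ax1.set_ylabel("log2 ratio")
    if maf is not None:
        het = maf.het
        xm = []
        for row in het.itertuples():
            sub = bins[(bins["chrom"] == row.chrom) & (bins["start"] <= row.pos) & (bins["end"] > row.pos)]
            xm.append(x[sub.index[0]] if len(sub) else np.nan)
        ax2.plot(xm, het["minor_fraction"], ".", ms=3, color="0.4")
    ax2.set_ylim(0, 0.55)
    ax2.set_ylabel("minor allele fraction")
    ax2.set_xlabel("genome bin index")
    if model is not None:
        ax1.set_title(
            f"purity={model.purity:.2f}  ploidy={model.ploidy:.2f}  source={model.source}"
        )
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
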