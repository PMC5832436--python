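"""Synthetic tumor specimens with known purity, ploidy, copy number and
variant truth.

The generator emulates a deep targeted-sequencing workup of an admixed
tumor: per-bin tumor/normal coverage whose log2-ratio is Gaussian around
the mixture expectation, genome-wide SNP allele depths that are binomial
around the mixture allele fraction, and candidate short variants drawn
binomially under their germline or (possibly subclonal) somatic
expectation.  Every specimen carries a truth table so that recovery can be
scored exactly.

Coordinates are synthetic: uniform-width bins laid out sequentially per
chromosome, 0-based half-open internally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    compute_ploidy,
    expected_af_germline,
    expected_af_somatic,
    expected_log_ratio,
    expected_maf,
)

__all__ = [
    "SegmentSpec",
    "VariantSpec",
    "SimulationConfig",
    "SpecimenData",
    "simulate_specimen",
    "simulate_cohort",
    "default_genome",
    "default_variants",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SegmentSpec:
    """One true copy-number segment: ``n_bins`` bins at state (C, M)."""

    chrom: str
    n_bins: int
    copy_number: int
    minor_count: int

    def validate(self) -> None:
        if self.n_bins < 1:
            raise ValueError(f"segment on {self.chrom}: n_bins must be >= 1")
        if self.copy_number < 0:
            raise ValueError(f"segment on {self.chrom}: copy number must be >= 0")
        if not (0 <= self.minor_count <= self.copy_number // 2):
            raise ValueError(
                f"segment on {self.chrom}: minor count {self.minor_count} "
                f"violates 0 <= M <= floor(C/2) for C={self.copy_number}"
            )


@dataclass(frozen=True)
class VariantSpec:
    """One simulated variant placed in ``segment_index`` of the genome.

    ``allele_count`` is the number of tumor copies carrying the alternate
    allele (V).  ``subclonal_fraction`` in (0, 1] scales the somatic tumor
    term; 1.0 means clonal.  Germline variants are always clonal.
    """

    segment_index: int
    origin: str  # "germline" | "somatic"
    allele_count: int
    subclonal_fraction: float = 1.0

    def validate(self, segments: list[SegmentSpec]) -> None:
        if self.origin not in ("germline", "somatic"):
            raise ValueError(f"unknown variant origin {self.origin!r}")
        if not (0 <= self.segment_index < len(segments)):
            raise ValueError(f"variant segment_index {self.segment_index} out of range")
        C = segments[self.segment_index].copy_number
        if not (0 <= self.allele_count <= C):
            raise ValueError(
                f"variant allele count V={self.allele_count} exceeds segment "
                f"copy number C={C}"
            )
        if self.origin == "somatic" and self.allele_count < 1:
            raise ValueError("somatic variants require V >= 1")
        if not (0.0 < self.subclonal_fraction <= 1.0):
            raise ValueError("subclonal_fraction must lie in (0, 1]")
        if self.origin == "germline" and self.subclonal_fraction != 1.0:
            raise ValueError("germline variants are clonal (subclonal_fraction = 1)")


@dataclass
class SimulationConfig:
    """Full description of one synthetic specimen.

    Defaults describe the operating regime the method targets: deep
    (~800x) targeted sequencing of a moderately aneuploid genome.
    """

    seed: int = 0
    purity: float = 0.5
    segments: list[SegmentSpec] = field(default_factory=lambda: default_genome())
    variants: list[VariantSpec] = field(default_factory=list)
    mean_depth: float = 800.0
    snps_per_segment: int = 15
    lr_noise_sd: float = 0.1
    het_snp_fraction: float = 0.6
    gc_bias_coefficients: list[float] | None = None
    bin_width: int = 1000
    hom_alt_error: float = 0.001

    def validate(self) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must lie in [0, 1]")
        if not self.segments:
            raise ValueError("at least one segment is required")
        for seg in self.segments:
            seg.validate()
        for v in self.variants:
            v.validate(self.segments)
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.lr_noise_sd < 0:
            raise ValueError("lr_noise_sd must be >= 0")
        if not (0.0 <= self.het_snp_fraction <= 1.0):
            raise ValueError("het_snp_fraction must lie in [0, 1]")

    def true_ploidy(self) -> float:
        lengths = [s.n_bins for s in self.segments]
        cns = [s.copy_number for s in self.segments]
        return compute_ploidy(lengths, cns)


@dataclass
class SpecimenData:
    """Raw inputs for one specimen plus (optionally) simulation truth.

    ``bins``:     chrom, start, end, gc, tumor_depth, normal_depth
    ``snps``:     chrom, pos, depth, alt_depth
    ``variants``: chrom, pos, ref, alt, depth, alt_depth, alt_frequency
    ``truth``:    dict with purity, ploidy, per-segment and per-variant tables
    """

    bins: pd.DataFrame
    snps: pd.DataFrame
    variants: pd.DataFrame
    truth: dict | None = None


def default_genome() -> list[SegmentSpec]:
    """A moderately aneuploid 22-chromosome synthetic genome.

    44 segments mixing diploid-het, copy-neutral LOH, single-copy loss,
    LOH gains and balanced amplification — the "22 to a few hundred"
    segment regime of real aneuploid panels.  Adjacent segments on a
    chromosome always differ in total copy number so every true
    breakpoint is visible to coverage-only segmentation.
    """
    spec = [
        ("chr1", 60, 2, 1), ("chr1", 60, 3, 1),
        ("chr2", 70, 2, 0), ("chr2", 50, 4, 1),
        ("chr3", 60, 1, 0), ("chr3", 60, 2, 1),
        ("chr4", 60, 4, 2), ("chr4", 60, 3, 0),
        ("chr5", 60, 2, 1), ("chr5", 60, 4, 1),
        ("chr6", 70, 2, 1), ("chr6", 50, 1, 0),
        ("chr7", 60, 2, 1), ("chr7", 60, 3, 1),
        ("chr8", 70, 2, 1), ("chr8", 50, 5, 2),
        ("chr9", 60, 2, 0), ("chr9", 60, 3, 1),
        ("chr10", 60, 3, 1), ("chr10", 60, 2, 1),
        ("chr11", 60, 4, 2), ("chr11", 60, 2, 1),
        ("chr12", 70, 1, 0), ("chr12", 50, 2, 1),
        ("chr13", 60, 2, 1), ("chr13", 60, 4, 0),
        ("chr14", 60, 2, 0), ("chr14", 60, 1, 0),
        ("chr15", 70, 2, 1), ("chr15", 50, 3, 0),
        ("chr16", 60, 3, 1), ("chr16", 60, 2, 1),
        ("chr17", 60, 1, 0), ("chr17", 60, 3, 1),
        ("chr18", 70, 2, 1), ("chr18", 50, 4, 2),
        ("chr19", 60, 2, 0), ("chr19", 60, 3, 1),
        ("chr20", 60, 2, 1), ("chr20", 60, 5, 1),
        ("chr21", 70, 2, 1), ("chr21", 50, 1, 0),
        ("chr22", 60, 3, 1), ("chr22", 60, 2, 1),
    ]
    return [SegmentSpec(*s) for s in spec]


def default_variants(segments: list[SegmentSpec] | None = None) -> list[VariantSpec]:
    """A panel of variants spanning the germline/somatic/zygosity space.

    Placed so that germline variants sit at V in {M, C-M, 0} and somatic at
    V in {M, C-M}\\{0} of their segment — the hypothesis space the caller
    searches.  Includes germline variants displaced by LOH/aneuploidy (the
    cases a naive AF-only rule misclassifies) and subclonal somatics.
    """
    if segments is None:
        segments = default_genome()
    out: list[VariantSpec] = []
    for i, seg in enumerate(segments):
        C, M = seg.copy_number, seg.minor_count
        major = C - M
        # one germline on the major allele of every segment
        if major >= 1:
            out.append(VariantSpec(i, "germline", major))
        # germline lost from tumor in LOH segments
        if M == 0 and C >= 1:
            out.append(VariantSpec(i, "germline", 0))
        elif M >= 1:
            out.append(VariantSpec(i, "germline", M))
        # one clonal somatic per segment (single hit on a major copy
        # where possible, else on the minor allele)
        if major >= 1:
            out.append(VariantSpec(i, "somatic", major))
        elif M >= 1:
            out.append(VariantSpec(i, "somatic", M))
        # a subclonal somatic in every third segment: a single-copy hit
        # present in half the tumor cells (the typical resistant-subclone
        # picture)
        if i % 3 == 0 and C >= 1:
            out.append(VariantSpec(i, "somatic", 1, subclonal_fraction=0.5))
    return out


def _segment_layout(config: SimulationConfig) -> pd.DataFrame:
    """Genomic intervals of the true segments (sequential per chromosome)."""
    rows = []
    offsets: dict[str, int] = {}
    for idx, seg in enumerate(config.segments):
        start = offsets.get(seg.chrom, 0)
        end = start + seg.n_bins * config.bin_width
        offsets[seg.chrom] = end
        rows.append(
            {
                "segment_index": idx,
                "chrom": seg.chrom,
                "start": start,
                "end": end,
                "n_bins": seg.n_bins,
                "C": seg.copy_number,
                "M": seg.minor_count,
            }
        )
    return pd.DataFrame(rows)


def simulate_specimen(config: SimulationConfig) -> SpecimenData:
    """Generate one specimen.  Same config (incl. seed) => identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.purity
    psi = config.true_ploidy()
    layout = _segment_layout(config)

    # --- coverage bins -------------------------------------------------
    bin_rows = []
    for seg, lay in zip(config.segments, layout.itertuples()):
        elr = float(expected_log_ratio(p, seg.copy_number, psi))
        starts = lay.start + np.arange(seg.n_bins) * config.bin_width
        gc = rng.uniform(0.35, 0.65, size=seg.n_bins)
        mean_tumor = config.mean_depth * 2.0 ** elr
        if config.gc_bias_coefficients is not None:
            mean_tumor = mean_tumor * np.polyval(config.gc_bias_coefficients, gc)
        noise = rng.normal(0.0, config.lr_noise_sd, size=seg.n_bins)
        tumor = np.rint(mean_tumor * 2.0 ** noise).astype(int)
        bin_rows.append(
            pd.DataFrame(
                {
                    "chrom": seg.chrom,
                    "start": starts,
                    "end": starts + config.bin_width,
                    "gc": gc,
                    "tumor_depth": np.maximum(tumor, 0),
                    "normal_depth": int(round(config.mean_depth)),
                }
            )
        )
    bins = pd.concat(bin_rows, ignore_index=True)

    # --- genome-wide SNPs ---------------------------------------------
    snp_rows = []
    for seg, lay in zip(config.segments, layout.itertuples()):
        n_snp = config.snps_per_segment
        if n_snp == 0:
            continue
        elr = float(expected_log_ratio(p, seg.copy_number, psi))
        pos = np.sort(
            rng.choice(np.arange(lay.start, lay.end), size=min(n_snp, lay.end - lay.start), replace=False)
        )
        depth = rng.poisson(config.mean_depth * 2.0 ** elr, size=pos.size)
        is_het = rng.random(pos.size) < config.het_snp_fraction
        emaf = float(expected_maf(p, seg.copy_number, seg.minor_count))
        if not np.isfinite(emaf):
            emaf = 0.0
        # unfolded orientation: alt allele on the minor or major haplotype
        flip = rng.random(pos.size) < 0.5
        q_het = np.where(flip, emaf, 1.0 - emaf)
        q = np.where(is_het, q_het, 1.0 - config.hom_alt_error)
        q = np.clip(q, 0.0, 1.0)
        alt = rng.binomial(np.maximum(depth, 0), q)
        snp_rows.append(
            pd.DataFrame(
                {"chrom": seg.chrom, "pos": pos, "depth": depth, "alt_depth": alt}
            )
        )
    snps = (
        pd.concat(snp_rows, ignore_index=True)
        if snp_rows
        else pd.DataFrame(columns=["chrom", "pos", "depth", "alt_depth"])
    )

    # --- candidate variants -------------------------------------------
    var_rows = []
    truth_rows = []
    for k, var in enumerate(config.variants):
        seg = config.segments[var.segment_index]
        lay = layout.iloc[var.segment_index]
        elr = float(expected_log_ratio(p, seg.copy_number, psi))
        pos = int(lay.start + (lay.end - lay.start) * (0.15 + 0.7 * rng.random()))
        if var.origin == "germline":
            q = float(expected_af_germline(p, seg.copy_number, var.allele_count))
        else:
            q = var.subclonal_fraction * float(
                expected_af_somatic(p, seg.copy_number, var.allele_count)
            )
        if not np.isfinite(q):
            q = 0.0
        q = float(np.clip(q, 0.0, 1.0))
        depth = max(int(rng.poisson(config.mean_depth * 2.0 ** elr)), 1)
        alt = int(rng.binomial(depth, q))
        ref_base = _BASES[k % 4]
        alt_base = _BASES[(k + 1) % 4]
        var_rows.append(
            {
                "chrom": seg.chrom,
                "pos": pos,
                "ref": ref_base,
                "alt": alt_base,
                "depth": depth,
                "alt_depth": alt,
                "alt_frequency": alt / depth,
            }
        )
        truth_rows.append(
            {
                "chrom": seg.chrom,
                "pos": pos,
                "ref": ref_base,
                "alt": alt_base,
                "origin": var.origin,
                "allele_count": var.allele_count,
                "subclonal_fraction": var.subclonal_fraction,
                "C": seg.copy_number,
                "M": seg.minor_count,
                "expected_af": q,
            }
        )
    variants = pd.DataFrame(
        var_rows,
        columns=["chrom", "pos", "ref", "alt", "depth", "alt_depth", "alt_frequency"],
    )
    truth = {
        "purity": p,
        "ploidy": psi,
        "seed": config.seed,
        "segments": layout,
        "variants": pd.DataFrame(
            truth_rows,
            columns=[
                "chrom", "pos", "ref", "alt", "origin", "allele_count",
                "subclonal_fraction", "C", "M", "expected_af",
            ],
        ),
    }
    return SpecimenData(bins=bins, snps=snps, variants=variants, truth=truth)


def simulate_cohort(
    config_template: SimulationConfig,
    n_specimens: int,
    purity_range,
    seed: int = 0,
) -> list[SpecimenData]:
    """Simulate a cohort over a purity titration.

    ``purity_range`` is either a (lo, hi) pair — purities are gridded
    evenly across it — or an explicit sequence of length ``n_specimens``
    (e.g. the 10/20/30/40/50/75% titration design).  Per-specimen seeds
    are derived deterministically from ``seed``.
    """
    if n_specimens < 1:
        raise ValueError("n_specimens must be >= 1")
    purities = np.asarray(purity_range, dtype=float)
    if purities.size == 0:
        raise ValueError("purity_range must not be empty")
    if purities.size == 2 and n_specimens != 2:
        purities = np.linspace(purities[0], purities[1], n_specimens)
    if purities.size != n_specimens:
        raise ValueError(
            "purity_range must be a (lo, hi) pair or a sequence of length n_specimens"
        )
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_specimens)
    out = []
    for pur, child in zip(purities, child_seeds):
        cfg = replace(config_template, purity=float(pur), seed=int(child))
        out.append(simulate_specimen(cfg))
    return out


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict form of a config (YAML-serializable)."""
    d = dataclasses.asdict(config)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["segments"] = [SegmentSpec(**s) for s in d.get("segments", [])]
    d["variants"] = [VariantSpec(**v) for v in d.get("variants", [])]
    return SimulationConfig(**d)
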