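"""Readers and writers for the pipeline's tabular and VCF artifacts.

TSV intervals are BED-style 0-based half-open; VCF positions are 1-based.
VCFs are written as plain uncompressed text and read back with cyvcf2.
"""

from __future__ import annotations

import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .cnmodel import CopyNumberModel
from .model import expected_log_ratio, expected_maf
from .segmentation import Segment, segments_from_frame, segments_to_frame

__all__ = [
    "write_coverage_tsv", "read_coverage_tsv",
    "write_snp_tsv", "read_snp_tsv",
    "write_segments_tsv", "read_segments_tsv",
    "write_variants_vcf", "read_variants_vcf",
    "write_calls", "read_calls_tsv",
    "write_model", "read_model",
    "write_specimen",
]


def write_coverage_tsv(bins: pd.DataFrame, path: str) -> None:
    cols = ["chrom", "start", "end", "gc", "tumor_depth", "normal_depth"]
    bins[cols].to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_snp_tsv(snps: pd.DataFrame, path: str) -> None:
    snps[["chrom", "pos", "depth", "alt_depth"]].to_csv(path, sep="\t", index=False)


def read_snp_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_segments_tsv(segments: list[Segment], path: str) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_segments_tsv(path: str) -> list[Segment]:
    return segments_from_frame(pd.read_csv(path, sep="\t"))


def _vcf_header(chroms: list[str], extra_info: bool = False) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=sgz",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele frequency">',
        '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alt read count">',
    ]
    if extra_info:
        lines += [
            '##INFO=<ID=SGZ_STATUS,Number=1,Type=String,Description="Somatic/germline status">',
            '##INFO=<ID=SGZ_ZYG,Number=1,Type=String,Description="Tumor zygosity">',
            '##INFO=<ID=SGZ_REASON,Number=1,Type=String,Description="No-call reason">',
            '##INFO=<ID=SGZ_PG,Number=1,Type=Float,Description="Two-tailed binomial p under germline hypothesis">',
            '##INFO=<ID=SGZ_PS,Number=1,Type=Float,Description="Two-tailed binomial p under somatic hypothesis">',
            '##INFO=<ID=SGZ_AFG,Number=1,Type=Float,Description="Expected germline AF">',
            '##INFO=<ID=SGZ_AFS,Number=1,Type=Float,Description="Expected somatic AF">',
        ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def write_variants_vcf(
    variants: pd.DataFrame, path: str, zero_based: bool = True
) -> None:
    """Write a minimal VCF; simulated 0-based positions become 1-based."""
    shift = 1 if zero_based else 0
    chroms = list(dict.fromkeys(variants["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write(_vcf_header(chroms))
        for row in variants.itertuples():
            info = f"DP={int(row.depth)};AF={row.alt_frequency:.6g};AO={int(row.alt_depth)}"
            fh.write(
                f"{row.chrom}\t{int(row.pos) + shift}\t.\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t{info}\n"
            )


def read_variants_vcf(path: str) -> pd.DataFrame:
    """Read variants (1-based pos) with DP/AF/AO INFO fields via cyvcf2."""
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(path):
        dp = rec.INFO.get("DP")
        af = rec.INFO.get("AF")
        ao = rec.INFO.get("AO")
        if dp is None or (af is None and ao is None):
            raise ValueError(f"variant record at {rec.CHROM}:{rec.POS} lacks DP/AF")
        dp = int(dp)
        if ao is None:
            ao = int(round(dp * float(af)))
        if af is None:
            af = int(ao) / dp if dp else 0.0
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "depth": dp,
                "alt_depth": int(ao),
                "alt_frequency": float(af),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "depth", "alt_depth", "alt_frequency"],
    )


def write_calls(calls_df: pd.DataFrame, tsv_path: str, vcf_path: str | None = None) -> None:
    """Write classified variants as a flat TSV and an annotated VCF mirror.

    ``calls_df`` positions are 1-based (VCF convention)."""
    calls_df.to_csv(tsv_path, sep="\t", index=False)
    if vcf_path is None:
        return
    chroms = list(dict.fromkeys(calls_df["chrom"].astype(str)))
    with open(vcf_path, "w") as fh:
        fh.write(_vcf_header(chroms, extra_info=True))
        for row in calls_df.itertuples():
            k = int(round(row.depth * row.alt_frequency))
            info = (
                f"DP={int(row.depth)};AF={row.alt_frequency:.6g};AO={k};"
                f"SGZ_STATUS={row.status};SGZ_ZYG={row.zygosity};SGZ_REASON={row.reason};"
                f"SGZ_PG={row.p_germline:.4g};SGZ_PS={row.p_somatic:.4g};"
                f"SGZ_AFG={row.af_germline:.4g};SGZ_AFS={row.af_somatic:.4g}"
            )
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\n"
            )


def read_calls_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_model(model: CopyNumberModel, segments: list[Segment], outdir: str) -> None:
    """Model as a YAML header plus a per-segment TSV."""
    os.makedirs(outdir, exist_ok=True)
    header = {
        "purity": float(model.purity),
        "ploidy": float(model.ploidy),
        "mse_lr": float(model.mse_lr),
        "mse_maf": None if np.isnan(model.mse_maf) else float(model.mse_maf),
        "source": model.source,
        "flags": list(model.flags),
    }
    with open(os.path.join(outdir, "model.yaml"), "w") as fh:
        yaml.safe_dump(header, fh, sort_keys=False)
    rows = []
    for seg, C, M in zip(segments, model.copy_number, model.minor_count):
        rows.append(
            {
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "n_bins": seg.n_bins,
                "median_lr": seg.median_lr,
                "sd_lr": seg.sd_lr,
                "n_snps": seg.n_snps,
                "maf_mean": seg.maf_mean,
                "sd_maf": seg.sd_maf,
                "C": int(C),
                "M": int(M),
                "expected_lr": float(expected_log_ratio(model.purity, C, model.ploidy)),
                "expected_maf": float(expected_maf(model.purity, C, M)),
            }
        )
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "model_segments.tsv"), sep="\t", index=False
    )


def read_model(outdir: str) -> tuple[CopyNumberModel, list[Segment]]:
    with open(os.path.join(outdir, "model.yaml")) as fh:
        header = yaml.safe_load(fh)
    df = pd.read_csv(os.path.join(outdir, "model_segments.tsv"), sep="\t")
    segments = segments_from_frame(df)
    model = CopyNumberModel(
        purity=float(header["purity"]),
        ploidy=float(header["ploidy"]),
        copy_number=df["C"].to_numpy(int),
        minor_count=df["M"].to_numpy(int),
        mse_lr=float(header["mse_lr"]),
        mse_maf=float("nan") if header["mse_maf"] is None else float(header["mse_maf"]),
        source=str(header["source"]),
        flags=list(header.get("flags") or []),
    )
    return model, segments


def write_specimen(specimen, outdir: str) -> dict:
    """Write one (possibly simulated) specimen's raw inputs; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "coverage": os.path.join(outdir, "coverage.tsv"),
        "snps": os.path.join(outdir, "snps.tsv"),
        "variants": os.path.join(outdir, "variants.vcf"),
    }
    write_coverage_tsv(specimen.bins, paths["coverage"])
    write_snp_tsv(specimen.snps, paths["snps"])
    write_variants_vcf(specimen.variants, paths["variants"], zero_based=True)
    if specimen.truth is not None:
        truth = specimen.truth
        paths["truth_segments"] = os.path.join(outdir, "truth_segments.tsv")
        paths["truth_variants"] = os.path.join(outdir, "truth_variants.tsv")
        paths["truth_meta"] = os.path.join(outdir, "truth_meta.yaml")
        truth["segments"].to_csv(paths["truth_segments"], sep="\t", index=False)
        truth["variants"].to_csv(paths["truth_variants"], sep="\t", index=False)
        with open(paths["truth_meta"], "w") as fh:
            yaml.safe_dump(
                {
                    "purity": float(truth["purity"]),
                    "ploidy": float(truth["ploidy"]),
                    "seed": int(truth["seed"]),
                },
                fh,
            )
    return paths
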