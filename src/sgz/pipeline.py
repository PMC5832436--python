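"""End-to-end orchestration: preprocess -> segment -> fit -> call.

Every stage writes its intermediate artifact (log-ratio TSV, SEG-like
segment table, model YAML/TSV, calls TSV + VCF) so stages are individually
inspectable and re-runnable; the whole run is reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as sgzio
from .cnmodel import CopyNumberEstimator
from .preprocess import compute_log_ratio, gc_correct, select_het_snps
from .segmentation import CBSSegmenter
from .sgzcall import SgzClassifier, calls_to_frame, variants_from_frame
from .simdata import SpecimenData

__all__ = ["RunConfig", "run_pipeline", "evaluate_against_truth", "evaluate_cohort"]

log = logging.getLogger("sgz")


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline; YAML round-trippable."""

    seed: int = 0
    # preprocessing
    min_snp_depth: int = 20
    het_lo: float = 0.10
    het_hi: float = 0.90
    lowess_frac: float = 0.3
    lowess_iterations: int = 1
    gc_correction: bool = True
    # segmentation
    cbs_alpha: float = 0.01
    n_perm: int = 1000
    min_bins: int = 10
    sd_lr_floor: float = 0.05
    sd_maf_floor: float = 0.02
    # copy-number model
    use_mcmc: bool = True
    c_max: int = 10
    lam: float = 1.0
    n_burn: int = 500
    n_samples: int = 500
    n_chains: int = 9
    loss_threshold: float = 0.10
    enable_high_purity_check: bool = True
    # calling
    alpha: float = 0.01
    purity_ceiling: float = 0.95
    subclonal_factor: float = 1.5
    subclonal_min_purity: float = 0.20
    zygosity_min_purity: float = 0.20
    misfit_nsd: float = 3.0
    basic_delta: float = 0.10
    # cohort
    e_g: float = 0.05
    e_s: float = 0.10

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def run_pipeline(
    specimen: SpecimenData,
    config: RunConfig | None = None,
    outdir: str | None = None,
    basic_method: bool = False,
) -> dict:
    """Run preprocess -> CBS -> copy-number fit -> variant calls.

    Returns a dict with the profiles, segments, fitted estimator, model,
    call records and (when the specimen has truth) an evaluation row.
    """
    config = config or RunConfig()
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        config.to_yaml(os.path.join(outdir, "run_config.yaml"))

    profile = compute_log_ratio(specimen.bins)
    if config.gc_correction:
        profile = gc_correct(
            profile, frac=config.lowess_frac, iterations=config.lowess_iterations
        )
    maf = select_het_snps(
        specimen.snps,
        min_depth=config.min_snp_depth,
        het_window=(config.het_lo, config.het_hi),
    )
    if outdir:
        profile.bins.to_csv(os.path.join(outdir, "log_ratio.tsv"), sep="\t", index=False)
        maf.snps.to_csv(os.path.join(outdir, "maf.tsv"), sep="\t", index=False)

    segmenter = CBSSegmenter(
        alpha=config.cbs_alpha,
        n_perm=config.n_perm,
        min_bins=config.min_bins,
        sd_lr_floor=config.sd_lr_floor,
        sd_maf_floor=config.sd_maf_floor,
        random_state=config.seed,
    ).fit(profile, maf)
    segments = segmenter.segments_
    if outdir:
        sgzio.write_segments_tsv(segments, os.path.join(outdir, "segments.tsv"))

    estimator = CopyNumberEstimator(
        use_mcmc=config.use_mcmc,
        c_max=config.c_max,
        lam=config.lam,
        n_burn=config.n_burn,
        n_samples=config.n_samples,
        n_chains=config.n_chains,
        loss_threshold=config.loss_threshold,
        enable_high_purity_check=config.enable_high_purity_check,
        random_state=config.seed,
    ).fit(segments, maf)
    model = estimator.model_
    log.info(
        "selected model: purity=%.3f ploidy=%.3f source=%s flags=%s",
        model.purity, model.ploidy, model.source, model.flags,
    )
    for entry in estimator.selection_log_:
        log.info("selection: %s", entry)
    if outdir:
        sgzio.write_model(model, segments, os.path.join(outdir, "model"))

    classifier = SgzClassifier(
        alpha=config.alpha,
        purity_ceiling=config.purity_ceiling,
        subclonal_factor=config.subclonal_factor,
        subclonal_min_purity=config.subclonal_min_purity,
        zygosity_min_purity=config.zygosity_min_purity,
        misfit_nsd=config.misfit_nsd,
        basic_method=basic_method,
        basic_delta=config.basic_delta,
    ).fit(model, segments)
    observations = variants_from_frame(specimen.variants, zero_based=True)
    calls = classifier.predict_calls(observations)
    calls_df = calls_to_frame(calls)
    if outdir:
        sgzio.write_calls(
            calls_df,
            os.path.join(outdir, "calls.tsv"),
            os.path.join(outdir, "calls.vcf"),
        )

    result = {
        "profile": profile,
        "maf": maf,
        "segments": segments,
        "estimator": estimator,
        "model": model,
        "calls": calls,
        "calls_df": calls_df,
    }
    if specimen.truth is not None:
        truth = specimen.truth["variants"].copy()
        truth["pos"] = truth["pos"] + 1  # calls are 1-based
        metrics = evaluate_against_truth(calls_df, truth)
        metrics["true_purity"] = specimen.truth["purity"]
        metrics["fitted_purity"] = model.purity
        result["evaluation"] = metrics
        if outdir:
            pd.DataFrame([metrics]).to_csv(
                os.path.join(outdir, "evaluation.tsv"), sep="\t", index=False
            )
    return result


def evaluate_against_truth(calls_df: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Call rate and per-origin accuracy against a simulation truth table.

    Call rate = called / (called + ambiguous).  Somatic accuracy = fraction
    of called true-somatic variants whose status is somatic or
    subclonal-somatic; germline accuracy analogous.  Accuracies are NaN
    when no variant of that origin received a call.
    """
    merged = calls_df.merge(
        truth[["chrom", "pos", "ref", "alt", "origin"]],
        on=["chrom", "pos", "ref", "alt"],
        how="inner",
        validate="one_to_one",
    )
    if len(merged) != len(calls_df):
        raise ValueError("truth table does not cover every call (key mismatch)")
    called = merged[merged["status"] != "ambiguous"]
    call_rate = len(called) / len(merged) if len(merged) else float("nan")
    som = called[called["origin"] == "somatic"]
    germ = called[called["origin"] == "germline"]
    som_acc = (
        som["status"].isin(["somatic", "subclonal_somatic"]).mean()
        if len(som)
        else float("nan")
    )
    germ_acc = (germ["status"] == "germline").mean() if len(germ) else float("nan")
    return {
        "n_variants": int(len(merged)),
        "n_called": int(len(called)),
        "call_rate": float(call_rate),
        "somatic_accuracy": float(som_acc),
        "germline_accuracy": float(germ_acc),
    }


def copy_number_accuracy(
    segments, model, truth_segments: pd.DataFrame
) -> float:
    """Bin-weighted fraction of the genome assigned its true copy number.

    Fitted segments are intersected with the truth intervals so the metric
    is robust to breakpoints merged or split by segmentation.
    """
    total = 0.0
    correct = 0.0
    for seg, C in zip(segments, model.copy_number):
        sub = truth_segments[truth_segments["chrom"] == seg.chrom]
        for row in sub.itertuples():
            ov = min(seg.end, row.end) - max(seg.start, row.start)
            if ov <= 0:
                continue
            total += ov
            if int(C) == int(row.C):
                correct += ov
    return correct / total if total else float("nan")


def evaluate_cohort(results: list[dict]) -> pd.DataFrame:
    """Stack per-specimen evaluation rows (e.g. across a purity titration)."""
    rows = [r["evaluation"] for r in results if "evaluation" in r]
    return pd.DataFrame(rows)
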