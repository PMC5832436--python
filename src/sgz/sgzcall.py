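"""Somatic / germline / subclonal-somatic classification of variants.

Given the fitted copy-number model, each variant's observed allele
fraction ``f`` at depth ``n`` is compared against its expected value under
the germline hypothesis (the normal contributes one alt copy) and the
somatic hypothesis (the normal contributes none), at its local segment's
(C, M).  The candidate tumor allele counts are V in {0, M, C-M} for
germline (V = 0 is "not in tumor") and V in {M, C-M}\\{0} for somatic.
Each hypothesis takes the V maximizing an exact two-tailed binomial
p-value; the four decision rules at significance level alpha then assign
somatic, germline, subclonal-somatic or ambiguous status, with zygosity
read off the winning V.

Gates: no status is called above 95% model purity (the germline/somatic
expectations converge); subclonal calls require purity above 20%;
zygosity is reported only at purity of at least 20%.

Classification depends on the copy-number model only through the expected
AF candidate sets (and the model purity for the gates), so models that are
mathematically equivalent in their expectations yield identical calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cnmodel import CopyNumberModel
from .model import expected_af_germline, expected_af_somatic, expected_log_ratio
from .segmentation import Segment

__all__ = [
    "VariantObservation",
    "SgzCall",
    "two_tailed_binomial_p",
    "classify_variant",
    "classify_zygosity",
    "basic_method_classify",
    "SgzClassifier",
    "calls_to_frame",
]

STATUSES = ("somatic", "germline", "subclonal_somatic", "ambiguous")
REASONS = (
    "none",
    "high_purity",
    "model_misfit",
    "compatible_with_both",
    "outside_both",
    "undefined_expectations",
)


@dataclass(frozen=True)
class VariantObservation:
    """One variant's read evidence: depth ``n`` and alt fraction ``f``.

    ``alt_depth`` is used as the binomial success count when available;
    otherwise ``round(n * f)`` reconstructs it.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    depth: int
    alt_frequency: float
    alt_depth: int | None = None

    def alt_reads(self) -> int:
        if self.alt_depth is not None:
            return int(self.alt_depth)
        return int(round(self.depth * self.alt_frequency))


@dataclass
class SgzCall:
    """Classification of one variant."""

    variant: VariantObservation
    status: str
    zygosity: str  # homozygous | heterozygous | not_in_tumor | subclonal | NA
    reason: str = "none"
    v_germline: int | None = None
    v_somatic: int | None = None
    af_germline: float = float("nan")
    af_somatic: float = float("nan")
    p_germline: float = float("nan")
    p_somatic: float = float("nan")
    segment_index: int | None = None


def two_tailed_binomial_p(k: int, n: int, q: float) -> float:
    """Exact two-tailed (minimum-likelihood) binomial test.

    Sums Binomial(n, q) probabilities over every outcome no more likely
    than the observed one (with a 1e-7 relative slack for floating-point
    ties): ``p = sum_j pmf(j) over {j : pmf(j) <= pmf(k) * (1 + 1e-7)}``.
    """
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    if q == 0.0:
        return 1.0 if k == 0 else 0.0
    if q == 1.0:
        return 1.0 if k == n else 0.0
    j = np.arange(n + 1)
    pmf = stats.binom.pmf(j, n, q)
    return float(pmf[pmf <= pmf[k] * (1.0 + 1e-7)].sum())


def classify_zygosity(V: int, C: int) -> str:
    """Tumor zygosity of a variant on V of C copies."""
    if not (0 <= V <= C):
        raise ValueError("V must lie in [0, C]")
    if V == 0:
        return "not_in_tumor"
    if V == C:
        return "homozygous"
    return "heterozygous"


def basic_method_classify(f: float, delta: float = 0.10) -> str:
    """AF-only comparator: germline when f is near 50% or near 100%,
    somatic otherwise.  Always calls (100% call rate)."""
    if not (0.0 <= f <= 1.0):
        raise ValueError("allele frequency must lie in [0, 1]")
    if abs(f - 0.5) <= delta or f >= 1.0 - delta:
        return "germline"
    return "somatic"


def _best_hypothesis(
    k: int, n: int, candidates: list[tuple[int, float]]
) -> tuple[int | None, float, float]:
    """(V, expected AF, p-value) of the candidate maximizing the binomial
    p-value; ties broken toward the smaller V for determinism."""
    best: tuple[int | None, float, float] = (None, float("nan"), 0.0)
    for V, af in sorted(candidates, key=lambda t: t[0]):
        if not np.isfinite(af):
            continue
        pv = two_tailed_binomial_p(k, n, float(np.clip(af, 0.0, 1.0)))
        if pv > best[2] * (1.0 + 1e-12):
            best = (V, af, pv)
    return best


def classify_from_expectations(
    n: int,
    k: int,
    germline_candidates: list[tuple[int, float]],
    somatic_candidates: list[tuple[int, float]],
    purity: float,
    C: int,
    alpha: float = 0.01,
    subclonal_factor: float = 1.5,
    subclonal_min_purity: float = 0.20,
    zygosity_min_purity: float = 0.20,
) -> SgzCall:
    """Core decision rules given the expected-AF candidate sets.

    Candidate lists hold ``(V, expected_af)`` pairs.  This function sees
    the model only through those expectations (plus purity for the gates
    and C for the zygosity label), which is what makes
    expectation-equivalent models produce identical calls.
    """
    f = k / n if n > 0 else 0.0
    vg, afg, pg = _best_hypothesis(k, n, germline_candidates)
    vs, afs, ps = _best_hypothesis(k, n, somatic_candidates)
    somatic_afs = [af for _, af in somatic_candidates if np.isfinite(af)]
    lowest_somatic_af = min(somatic_afs) if somatic_afs else float("nan")

    status, zyg, reason = "ambiguous", "NA", "none"
    win_v: int | None = None
    if ps > alpha and pg <= alpha:
        status, win_v = "somatic", vs
    elif pg > alpha and ps <= alpha:
        status, win_v = "germline", vg
    elif (
        pg <= alpha
        and ps <= alpha
        and np.isfinite(lowest_somatic_af)
        and f < lowest_somatic_af / subclonal_factor
        and purity > subclonal_min_purity
    ):
        status = "subclonal_somatic"
    elif pg > alpha and ps > alpha:
        reason = "compatible_with_both"
    else:
        reason = "outside_both"

    if status == "subclonal_somatic":
        zyg = "subclonal"
    elif win_v is not None:
        zyg = classify_zygosity(win_v, C)
    if purity < zygosity_min_purity:
        zyg = "NA"

    dummy = VariantObservation("", 0, "", "", n, f, k)
    return SgzCall(
        variant=dummy,
        status=status,
        zygosity=zyg,
        reason=reason if status == "ambiguous" else "none",
        v_germline=vg,
        v_somatic=vs,
        af_germline=afg,
        af_somatic=afs,
        p_germline=pg,
        p_somatic=ps,
    )


def assign_segment(
    variant: VariantObservation, segments: list[Segment]
) -> int | None:
    """Index of the segment containing the variant; if none contains it,
    the nearest segment on the same chromosome by midpoint; None if the
    chromosome is unmodeled."""
    pos0 = variant.pos - 1  # internal 0-based
    best, best_dist = None, None
    for i, seg in enumerate(segments):
        if seg.chrom != variant.chrom:
            continue
        if seg.start <= pos0 < seg.end:
            return i
        mid = 0.5 * (seg.start + seg.end)
        dist = abs(pos0 - mid)
        if best_dist is None or dist < best_dist:
            best, best_dist = i, dist
    return best


def classify_variant(
    variant: VariantObservation,
    model: CopyNumberModel,
    segments: list[Segment],
    alpha: float = 0.01,
    purity_ceiling: float = 0.95,
    subclonal_factor: float = 1.5,
    subclonal_min_purity: float = 0.20,
    zygosity_min_purity: float = 0.20,
    misfit_nsd: float = 3.0,
) -> SgzCall:
    """Classify one variant under the fitted copy-number model.

    Order of gates: near-pure specimens (purity above ``purity_ceiling``)
    are never called; a variant whose segment's observed log-ratio
    deviates grossly (more than ``misfit_nsd`` segment SDs) from the model
    expectation, or that falls outside every modeled segment, is a
    model-misfit no-call; the p = 1, C = 0 degeneracy has undefined
    expectations.  Otherwise the binomial decision rules apply.
    """
    p = model.purity
    n = variant.depth
    k = variant.alt_reads()
    if not (0 <= k <= n):
        raise ValueError("alt reads outside [0, depth]")

    def no_call(reason: str, seg_idx: int | None = None) -> SgzCall:
        call = SgzCall(
            variant=variant, status="ambiguous", zygosity="NA", reason=reason,
            segment_index=seg_idx,
        )
        return call

    if p > purity_ceiling:
        return no_call("high_purity")
    seg_idx = assign_segment(variant, segments)
    if seg_idx is None:
        return no_call("model_misfit")
    seg = segments[seg_idx]
    C = int(model.copy_number[seg_idx])
    M = int(model.minor_count[seg_idx])
    exp_lr = float(expected_log_ratio(p, C, model.ploidy))
    if not np.isfinite(exp_lr):
        return no_call("undefined_expectations", seg_idx)
    if abs(seg.median_lr - exp_lr) > misfit_nsd * seg.sd_lr:
        return no_call("model_misfit", seg_idx)

    v_germ = sorted({0, M, C - M})
    v_som = sorted({M, C - M} - {0})
    germ_c = [(v, float(expected_af_germline(p, C, v))) for v in v_germ]
    som_c = [(v, float(expected_af_somatic(p, C, v))) for v in v_som]
    if not any(np.isfinite(af) for _, af in germ_c + som_c):
        return no_call("undefined_expectations", seg_idx)

    core = classify_from_expectations(
        n,
        k,
        germ_c,
        som_c,
        purity=p,
        C=C,
        alpha=alpha,
        subclonal_factor=subclonal_factor,
        subclonal_min_purity=subclonal_min_purity,
        zygosity_min_purity=zygosity_min_purity,
    )
    core.variant = variant
    core.segment_index = seg_idx
    return core


class SgzClassifier(BaseEstimator):
    """Variant classifier over a fitted copy-number model.

    ``fit(model, segments)`` binds the genome-wide model;
    ``predict(variants)`` returns the status array and
    ``predict_calls(variants)`` the full :class:`SgzCall` records.
    With ``basic_method=True`` predictions use the AF-only comparator
    instead (near-50%/near-100% germline rule).
    """

    def __init__(
        self,
        alpha: float = 0.01,
        purity_ceiling: float = 0.95,
        subclonal_factor: float = 1.5,
        subclonal_min_purity: float = 0.20,
        zygosity_min_purity: float = 0.20,
        misfit_nsd: float = 3.0,
        basic_method: bool = False,
        basic_delta: float = 0.10,
    ):
        self.alpha = alpha
        self.purity_ceiling = purity_ceiling
        self.subclonal_factor = subclonal_factor
        self.subclonal_min_purity = subclonal_min_purity
        self.zygosity_min_purity = zygosity_min_purity
        self.misfit_nsd = misfit_nsd
        self.basic_method = basic_method
        self.basic_delta = basic_delta

    def fit(self, model: CopyNumberModel, segments: list[Segment] | None = None):
        self.model_ = model
        self.segments_ = segments if segments is not None else []
        return self

    def predict_calls(self, variants: list[VariantObservation]) -> list[SgzCall]:
        if self.basic_method:
            out = []
            for v in variants:
                status = basic_method_classify(v.alt_frequency, self.basic_delta)
                out.append(
                    SgzCall(variant=v, status=status, zygosity="NA", reason="none")
                )
            return out
        if not hasattr(self, "model_"):
            raise ValueError("SgzClassifier must be fit with a CopyNumberModel first")
        return [
            classify_variant(
                v,
                self.model_,
                self.segments_,
                alpha=self.alpha,
                purity_ceiling=self.purity_ceiling,
                subclonal_factor=self.subclonal_factor,
                subclonal_min_purity=self.subclonal_min_purity,
                zygosity_min_purity=self.zygosity_min_purity,
                misfit_nsd=self.misfit_nsd,
            )
            for v in variants
        ]

    def predict(self, variants: list[VariantObservation]) -> np.ndarray:
        return np.asarray([c.status for c in self.predict_calls(variants)])


def variants_from_frame(
    df: pd.DataFrame, zero_based: bool = False
) -> list[VariantObservation]:
    """Build observations from a variants table (chrom, pos, ref, alt,
    depth, alt_frequency[, alt_depth]).  ``VariantObservation.pos`` is
    1-based (the VCF convention); pass ``zero_based=True`` for tables in
    internal 0-based coordinates (e.g. straight from the simulator)."""
    out = []
    has_ad = "alt_depth" in df.columns
    shift = 1 if zero_based else 0
    for row in df.itertuples():
        out.append(
            VariantObservation(
                chrom=str(row.chrom),
                pos=int(row.pos) + shift,
                ref=str(row.ref),
                alt=str(row.alt),
                depth=int(row.depth),
                alt_frequency=float(row.alt_frequency),
                alt_depth=int(row.alt_depth) if has_ad else None,
            )
        )
    return out


def calls_to_frame(calls: list[SgzCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "depth": c.variant.depth,
                "alt_frequency": c.variant.alt_frequency,
                "status": c.status,
                "zygosity": c.zygosity,
                "reason": c.reason,
                "v_germline": c.v_germline,
                "v_somatic": c.v_somatic,
                "af_germline": c.af_germline,
                "af_somatic": c.af_somatic,
                "p_germline": c.p_germline,
                "p_somatic": c.p_somatic,
            }
            for c in calls
        ]
    )
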