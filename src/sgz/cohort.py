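"""Cohort-level Bayesian re-annotation of recurrent variants.

A variant called across many specimens accumulates ``n_G`` germline and
``n_S`` somatic calls (subclonal-somatic counts as somatic; ambiguous
calls are tallied but carry no likelihood weight).  With a flat prior and
per-call error rates ``e_G`` (probability a germline prediction is wrong)
and ``e_S`` (probability a somatic prediction is wrong), the counts are
binomial under each origin hypothesis and the posterior probability of
somatic origin is

    P(S | n_G, n_S) = P(n_G, n_S | S) / [P(n_G, n_S | G) + P(n_G, n_S | S)]

with P(n_G,n_S|G) = C(n_G+n_S, n_G) e_G^{n_S} (1-e_G)^{n_G} and
P(n_G,n_S|S) = C(n_G+n_S, n_S) e_S^{n_G} (1-e_S)^{n_S}.  Defaults use the
conservative error rates e_G = 0.05, e_S = 0.10.  All arithmetic is done
in log space so posteriors remain finite at thousands of observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = ["CohortTally", "cohort_posterior", "tally_calls", "tallies_to_frame"]

DEFAULT_E_G = 0.05
DEFAULT_E_S = 0.10


@dataclass
class CohortTally:
    chrom: str
    pos: int
    ref: str
    alt: str
    n_germline: int
    n_somatic: int
    n_ambiguous: int
    e_g: float
    e_s: float
    p_somatic: float
    p_germline: float


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def _xlogy(x: float, y: float) -> float:
    # 0 * log(0) := 0, so zero error rates stay well-defined
    if x == 0:
        return 0.0
    return x * np.log(y)


def cohort_posterior(
    n_G: int, n_S: int, e_G: float = DEFAULT_E_G, e_S: float = DEFAULT_E_S
) -> tuple[float, float]:
    """(P_somatic, P_germline) given the call counts; flat prior.

    Underflow-safe: evaluated in log space, finite even at tens of
    thousands of observations.
    """
    if n_G < 0 or n_S < 0:
        raise ValueError("call counts must be non-negative")
    if not (0.0 <= e_G < 1.0 and 0.0 <= e_S < 1.0):
        raise ValueError("error rates must lie in [0, 1)")
    n = n_G + n_S
    lg = _log_binom(n, n_G) + _xlogy(n_S, e_G) + _xlogy(n_G, 1.0 - e_G)
    ls = _log_binom(n, n_S) + _xlogy(n_G, e_S) + _xlogy(n_S, 1.0 - e_S)
    norm = logsumexp([lg, ls])
    p_som = float(np.exp(ls - norm))
    p_germ = float(np.exp(lg - norm))
    return p_som, p_germ


def tally_calls(
    calls: pd.DataFrame, e_G: float = DEFAULT_E_G, e_S: float = DEFAULT_E_S
) -> list[CohortTally]:
    """Tally per-sample statuses per variant key and compute posteriors.

    ``calls`` needs columns chrom, pos, ref, alt, status (one row per
    sample-variant).  Subclonal-somatic counts toward ``n_S``; ambiguous
    rows are counted separately and excluded from the likelihood.
    """
    if calls.empty:
        return []
    required = {"chrom", "pos", "ref", "alt", "status"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls table lacks columns: {sorted(missing)}")
    out: list[CohortTally] = []
    for (chrom, pos, ref, alt), sub in calls.groupby(
        ["chrom", "pos", "ref", "alt"], sort=True
    ):
        status = sub["status"]
        n_g = int((status == "germline").sum())
        n_s = int(status.isin(["somatic", "subclonal_somatic"]).sum())
        n_a = int((status == "ambiguous").sum())
        p_som, p_germ = cohort_posterior(n_g, n_s, e_G, e_S)
        out.append(
            CohortTally(
                chrom=str(chrom), pos=int(pos), ref=str(ref), alt=str(alt),
                n_germline=n_g, n_somatic=n_s, n_ambiguous=n_a,
                e_g=e_G, e_s=e_S, p_somatic=p_som, p_germline=p_germ,
            )
        )
    return out


def tallies_to_frame(tallies: list[CohortTally]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": t.chrom,
                "pos": t.pos,
                "ref": t.ref,
                "alt": t.alt,
                "n_germline": t.n_germline,
                "n_somatic": t.n_somatic,
                "n_ambiguous": t.n_ambiguous,
                "p_somatic": t.p_somatic,
                "p_germline": t.p_germline,
            }
            for t in tallies
        ]
    )
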