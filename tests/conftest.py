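"""Shared fixtures: simulated specimens and fitted pipelines.

Expensive artifacts (full pipeline runs) are session-scoped so several
test modules can share one fit.
"""

from __future__ import annotations

import numpy as np
import pytest

from sgz.cnmodel import CopyNumberModel
from sgz.pipeline import RunConfig, run_pipeline
from sgz.segmentation import Segment
from sgz.simdata import (
    SegmentSpec,
    SimulationConfig,
    default_variants,
    simulate_specimen,
)


@pytest.fixture(scope="session")
def small_genome():
    """A compact 4-chromosome aneuploid genome for fast tests."""
    return [
        SegmentSpec("chr1", 40, 2, 1),
        SegmentSpec("chr1", 40, 3, 1),
        SegmentSpec("chr2", 40, 2, 0),
        SegmentSpec("chr2", 40, 4, 1),
        SegmentSpec("chr3", 40, 1, 0),
        SegmentSpec("chr3", 40, 2, 1),
        SegmentSpec("chr4", 40, 4, 2),
        SegmentSpec("chr4", 40, 2, 1),
    ]


@pytest.fixture(scope="session")
def specimen_mid(small_genome):
    """Purity-0.5 specimen on the small genome with a variant panel."""
    cfg = SimulationConfig(
        seed=11, purity=0.5, segments=small_genome,
        variants=default_variants(small_genome),
    )
    return simulate_specimen(cfg)


@pytest.fixture(scope="session")
def pipeline_mid(specimen_mid):
    """Full pipeline result on the purity-0.5 specimen."""
    return run_pipeline(specimen_mid, RunConfig(seed=11))


def make_single_segment_model(
    purity: float, C: int, M: int, ploidy: float | None = None
) -> tuple[CopyNumberModel, list[Segment]]:
    """A one-segment model whose observed log-ratio equals its expectation,
    so classification is exercised without misfit gating."""
    from sgz.model import expected_log_ratio, expected_maf

    psi = float(C) if ploidy is None else ploidy
    model = CopyNumberModel(
        purity=purity,
        ploidy=psi,
        copy_number=np.array([C]),
        minor_count=np.array([M]),
    )
    seg = Segment(
        chrom="chr1",
        start=0,
        end=1_000_000,
        n_bins=100,
        median_lr=float(expected_log_ratio(purity, C, psi)),
        sd_lr=0.05,
        maf_mean=float(expected_maf(purity, C, M)),
        sd_maf=0.02,
        n_snps=10,
    )
    return model, [seg]
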