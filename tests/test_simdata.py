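"""Simulator: determinism, validation, and convergence to the model means."""

import numpy as np
import pandas as pd
import pytest

from sgz.model import expected_log_ratio, expected_maf
from sgz.simdata import (
    SegmentSpec,
    SimulationConfig,
    VariantSpec,
    simulate_cohort,
    simulate_specimen,
)


def test_same_seed_same_output(small_genome):
    cfg = SimulationConfig(seed=5, purity=0.4, segments=small_genome,
                           variants=[VariantSpec(0, "germline", 1)])
    a = simulate_specimen(cfg)
    b = simulate_specimen(cfg)
    pd.testing.assert_frame_equal(a.bins, b.bins)
    pd.testing.assert_frame_equal(a.snps, b.snps)
    pd.testing.assert_frame_equal(a.variants, b.variants)


@pytest.mark.parametrize(
    "variant",
    [
        VariantSpec(0, "germline", 5),     # V > C
        VariantSpec(0, "somatic", 0),      # somatic needs V >= 1
        VariantSpec(0, "somatic", 1, 0.0), # subclonal fraction outside (0, 1]
        VariantSpec(0, "germline", 1, 0.5),# germline must be clonal
    ],
)
def test_inconsistent_variant_spec_rejected(variant):
    cfg = SimulationConfig(
        segments=[SegmentSpec("chr1", 10, 2, 1)], variants=[variant]
    )
    with pytest.raises(ValueError):
        cfg.validate()


def test_invalid_minor_count_rejected():
    with pytest.raises(ValueError):
        SegmentSpec("chr1", 10, 2, 2).validate()


def test_pure_normal_specimen_is_flat_and_het():
    """At purity 0 every expected log-ratio is 0 and a germline het variant
    concentrates near allele fraction 0.5."""
    segs = [SegmentSpec("chr1", 200, 2, 1)]
    cfg = SimulationConfig(
        seed=3, purity=0.0, segments=segs, mean_depth=2000,
        variants=[VariantSpec(0, "germline", 1)],
    )
    sp = simulate_specimen(cfg)
    lr = np.log2(sp.bins["tumor_depth"] / sp.bins["normal_depth"])
    assert abs(lr.mean()) < 0.02
    assert sp.variants["alt_frequency"].iloc[0] == pytest.approx(0.5, abs=0.05)


def test_pure_tumor_amplified_segment_log_ratio():
    """Purity 1, C=4 on a ploidy-2 genome: that segment's mean log-ratio
    converges to 1.0 (log2 of 4/2)."""
    segs = [SegmentSpec("chr1", 400, 4, 2), SegmentSpec("chr2", 800, 1, 0)]
    cfg = SimulationConfig(seed=9, purity=1.0, segments=segs)
    assert cfg.true_ploidy() == pytest.approx(2.0)
    sp = simulate_specimen(cfg)
    sub = sp.bins[sp.bins["chrom"] == "chr1"]
    lr = np.log2(sub["tumor_depth"] / sub["normal_depth"])
    assert lr.mean() == pytest.approx(1.0, abs=0.02)


def test_somatic_clonal_alt_fraction_monte_carlo():
    """p=0.5, C=2/M=1, clonal somatic V=1 at depth 10^4: the mean alt
    fraction over 200 replicates matches the somatic expectation 0.25."""
    segs = [SegmentSpec("chr1", 5, 2, 1)]
    cfg = SimulationConfig(
        seed=21, purity=0.5, segments=segs, mean_depth=10_000,
        snps_per_segment=0,
        variants=[VariantSpec(0, "somatic", 1)] * 200,
    )
    sp = simulate_specimen(cfg)
    assert sp.variants["alt_frequency"].mean() == pytest.approx(0.25, abs=0.01)


def test_snp_maf_converges_to_model_mean():
    """Per-segment mean folded MAF at depth 10^4 approaches the mixture
    expectation within 0.01 (balanced and LOH segments)."""
    segs = [SegmentSpec("chr1", 60, 2, 1), SegmentSpec("chr2", 60, 2, 0)]
    cfg = SimulationConfig(
        seed=13, purity=0.5, segments=segs, mean_depth=10_000,
        snps_per_segment=60, het_snp_fraction=1.0,
    )
    sp = simulate_specimen(cfg)
    for chrom, (C, M) in [("chr1", (2, 1)), ("chr2", (2, 0))]:
        sub = sp.snps[sp.snps["chrom"] == chrom]
        af = sub["alt_depth"] / sub["depth"]
        folded = np.minimum(af, 1 - af)
        want = float(expected_maf(0.5, C, M))
        assert folded.mean() == pytest.approx(want, abs=0.01)


def test_bin_log_ratio_converges_to_model_mean():
    """Mean per-segment log-ratio over ~10^3 bins matches the expectation
    within 0.02."""
    segs = [SegmentSpec("chr1", 1000, 3, 1), SegmentSpec("chr2", 1000, 2, 1)]
    cfg = SimulationConfig(seed=2, purity=0.6, segments=segs)
    psi = cfg.true_ploidy()
    sp = simulate_specimen(cfg)
    for chrom, C in [("chr1", 3), ("chr2", 2)]:
        sub = sp.bins[sp.bins["chrom"] == chrom]
        lr = np.log2(sub["tumor_depth"] / sub["normal_depth"])
        assert lr.mean() == pytest.approx(
            float(expected_log_ratio(0.6, C, psi)), abs=0.02
        )


def test_truth_table_round_trips(small_genome):
    from sgz.simdata import default_variants

    variants = default_variants(small_genome)
    cfg = SimulationConfig(seed=4, purity=0.4, segments=small_genome, variants=variants)
    sp = simulate_specimen(cfg)
    truth = sp.truth["variants"]
    assert len(truth) == len(variants)
    for spec_v, row in zip(variants, truth.itertuples()):
        assert row.origin == spec_v.origin
        assert row.allele_count == spec_v.allele_count
        assert row.subclonal_fraction == spec_v.subclonal_fraction
    # every simulated variant is recoverable from the truth table by position
    merged = sp.variants.merge(truth, on=["chrom", "pos", "ref", "alt"])
    assert len(merged) == len(sp.variants)


def test_cohort_titration_purities(small_genome):
    tpl = SimulationConfig(segments=small_genome)
    purities = [0.10, 0.20, 0.30, 0.40, 0.50, 0.75]
    cohort = simulate_cohort(tpl, 6, purities, seed=8)
    assert [sp.truth["purity"] for sp in cohort] == purities
    again = simulate_cohort(tpl, 6, purities, seed=8)
    for a, b in zip(cohort, again):
        pd.testing.assert_frame_equal(a.bins, b.bins)
        pd.testing.assert_frame_equal(a.variants, b.variants)


def test_cohort_single_specimen_matches_direct_call(small_genome):
    tpl = SimulationConfig(segments=small_genome)
    [sp] = simulate_cohort(tpl, 1, [0.33], seed=5)
    seed = sp.truth["seed"]
    from dataclasses import replace

    direct = simulate_specimen(replace(tpl, purity=0.33, seed=seed))
    pd.testing.assert_frame_equal(sp.bins, direct.bins)


def test_cohort_rejects_empty_purity_range(small_genome):
    tpl = SimulationConfig(segments=small_genome)
    with pytest.raises(ValueError):
        simulate_cohort(tpl, 2, [], seed=0)
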