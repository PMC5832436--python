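"""Copy-number model fitting: scoring, grid search, sampler, selection."""

import numpy as np
import pytest

from sgz.cnmodel import (
    CopyNumberEstimator,
    CopyNumberModel,
    grid_fit,
    high_purity_check,
    log_posterior,
    mcmc_fit,
    score_model,
    select_model,
)
from sgz.model import compute_ploidy, expected_log_ratio, expected_maf
from sgz.preprocess import compute_log_ratio, gc_correct, select_het_snps
from sgz.segmentation import CBSSegmenter, Segment
from sgz.simdata import SimulationConfig, simulate_specimen


def _toy_segments(p, states, psi=None, n_bins=50, n_snps=10):
    """Segments whose summaries sit exactly at the model expectations."""
    Cs = [c for c, _ in states]
    psi = compute_ploidy([n_bins] * len(states), Cs) if psi is None else psi
    segs = []
    for i, (C, M) in enumerate(states):
        segs.append(
            Segment(
                chrom=f"chr{i+1}",
                start=0,
                end=n_bins * 1000,
                n_bins=n_bins,
                median_lr=float(expected_log_ratio(p, C, psi)),
                sd_lr=0.05,
                maf_mean=float(expected_maf(p, C, M)),
                sd_maf=0.02,
                n_snps=n_snps,
            )
        )
    return segs, psi


def _truth_model(p, states, lengths):
    C = np.array([c for c, _ in states])
    M = np.array([m for _, m in states])
    return CopyNumberModel(
        purity=p, ploidy=compute_ploidy(lengths, C), copy_number=C, minor_count=M
    )


def test_truth_model_scores_zero_on_exact_data():
    states = [(2, 1), (3, 1), (1, 0)]
    segs, _ = _toy_segments(0.6, states)
    model = _truth_model(0.6, states, [50] * 3)
    mse_lr, mse_maf = score_model(model, segs)
    assert mse_lr == pytest.approx(0.0, abs=1e-18)
    assert mse_maf == pytest.approx(0.0, abs=1e-18)


def test_perturbing_copy_number_increases_error():
    states = [(2, 1), (3, 1), (1, 0)]
    segs, _ = _toy_segments(0.6, states)
    model = _truth_model(0.6, states, [50] * 3)
    base, _ = score_model(model, segs)
    worse = CopyNumberModel(
        purity=0.6, ploidy=model.ploidy,
        copy_number=model.copy_number + np.array([1, 0, 0]),
        minor_count=model.minor_count,
    )
    worse_lr, _ = score_model(worse, segs)
    assert worse_lr > base


def test_score_matches_hand_computation():
    """Two segments, hand-evaluated length-weighted squared errors."""
    p, psi = 0.5, 2.5
    seg1 = Segment("chr1", 0, 30_000, 30, 0.10, 0.05, maf_mean=0.40, sd_maf=0.02, n_snps=5)
    seg2 = Segment("chr2", 0, 10_000, 10, -0.20, 0.05, maf_mean=float("nan"), sd_maf=float("nan"), n_snps=0)
    model = CopyNumberModel(p, psi, np.array([3, 2]), np.array([1, 1]))
    e1 = float(expected_log_ratio(p, 3, psi))
    e2 = float(expected_log_ratio(p, 2, psi))
    want_lr = (30 * (0.10 - e1) ** 2 + 10 * (-0.20 - e2) ** 2) / 40
    want_maf = (0.40 - float(expected_maf(p, 3, 1))) ** 2
    mse_lr, mse_maf = score_model(model, [seg1, seg2])
    assert mse_lr == pytest.approx(want_lr, rel=1e-12)
    assert mse_maf == pytest.approx(want_maf, rel=1e-12)


def test_grid_recovers_noise_free_model():
    states = [(2, 1), (3, 1), (1, 0), (4, 2), (2, 0), (5, 2), (2, 1), (3, 0)]
    segs, _ = _toy_segments(0.6, states)
    best = grid_fit(segs)[0]
    assert best.purity == pytest.approx(0.6, abs=0.011)
    assert list(best.copy_number) == [c for c, _ in states]
    assert list(best.minor_count) == [m for _, m in states]


def test_flat_genome_flagged_non_identifiable():
    states = [(2, 1)] * 6
    segs, _ = _toy_segments(0.5, states)
    cands = grid_fit(segs)
    assert any("non_identifiable" in c.flags for c in cands)


def test_single_segment_flagged_degenerate():
    segs, _ = _toy_segments(0.5, [(2, 1)])
    cands = grid_fit(segs)
    assert cands and all("degenerate_single_segment" in c.flags for c in cands)


def test_ploidy_invariant_on_every_model(specimen_mid, pipeline_mid):
    for model in [pipeline_mid["model"]] + pipeline_mid["estimator"].candidates_[:3]:
        lengths = [s.length for s in pipeline_mid["segments"]]
        assert model.ploidy == pytest.approx(
            compute_ploidy(lengths, model.copy_number), abs=1e-9
        )


def test_mcmc_recovers_noise_free_model():
    states = [(2, 1), (3, 1), (1, 0), (4, 2), (2, 0), (5, 2), (2, 1), (3, 0),
              (2, 1), (4, 1), (2, 1), (1, 0), (3, 1), (2, 0), (2, 1), (4, 2),
              (3, 1), (2, 1), (5, 1), (2, 1)]
    segs, _ = _toy_segments(0.5, states)
    model = mcmc_fit(segs, random_state=0)
    assert model.purity == pytest.approx(0.5, abs=0.02)
    assert list(model.copy_number) == [c for c, _ in states]
    assert list(model.minor_count) == [m for _, m in states]


def test_chains_merge_on_well_identified_specimen(small_genome):
    """Dispersed-start chains agree (split-Rhat <= 1.1) when the data
    clearly identify the model."""
    sp = simulate_specimen(
        SimulationConfig(seed=1, purity=0.7, segments=small_genome)
    )
    prof = compute_log_ratio(sp.bins)
    maf = select_het_snps(sp.snps)
    segs = CBSSegmenter(random_state=1).fit(prof, maf).segments_
    model = mcmc_fit(segs, random_state=1)
    assert model.rhat_purity <= 1.1
    assert "mcmc_nonconverged" not in model.flags
    assert model.purity == pytest.approx(0.7, abs=0.03)


def test_mcmc_deterministic_given_seed():
    states = [(2, 1), (3, 1), (1, 0), (4, 2)]
    segs, _ = _toy_segments(0.4, states)
    a = mcmc_fit(segs, n_burn=100, n_samples=100, n_chains=2, random_state=5)
    b = mcmc_fit(segs, n_burn=100, n_samples=100, n_chains=2, random_state=5)
    assert a.purity == b.purity
    assert np.array_equal(a.copy_number, b.copy_number)
    assert np.array_equal(a.minor_count, b.minor_count)


def test_grid_and_mcmc_agree_noise_free():
    states = [(2, 1), (3, 1), (1, 0), (4, 2), (2, 0), (3, 0), (2, 1), (4, 1)]
    segs, _ = _toy_segments(0.45, states)
    g = grid_fit(segs)[0]
    m = mcmc_fit(segs, random_state=1)
    assert np.array_equal(g.copy_number, m.copy_number)
    assert np.array_equal(g.minor_count, m.minor_count)
    assert abs(g.purity - m.purity) <= 0.02


def test_selection_prefers_better_grid_candidate():
    """A grid candidate reducing both MSEs with sane ploidy, loss, and
    complexity replaces the sampler's model."""
    states = [(2, 1), (3, 1), (1, 0), (4, 2), (2, 0), (3, 0)]
    segs, _ = _toy_segments(0.7, states)
    lengths = [s.length for s in segs]
    truth = _truth_model(0.7, states, lengths)
    truth.mse_lr, truth.mse_maf = score_model(truth, segs)
    wrong_states = [(2, 1), (3, 1), (1, 0), (4, 2), (3, 1), (3, 0)]
    gibbs = _truth_model(0.7, wrong_states, lengths)
    gibbs.source = "gibbs"
    gibbs.mse_lr, gibbs.mse_maf = score_model(gibbs, segs)
    chosen, log = select_model(gibbs, [truth], segs)
    assert chosen is truth
    assert log[0]["rule1_mse_reduced"] and log[0]["rule4_not_more_complex"]


def test_selection_rejects_low_ploidy_candidate():
    states = [(2, 1), (3, 1), (2, 0), (4, 1)]
    segs, _ = _toy_segments(0.6, states)
    lengths = [s.length for s in segs]
    gibbs = _truth_model(0.6, states, lengths)
    gibbs.source = "gibbs"
    gibbs.mse_lr, gibbs.mse_maf = score_model(gibbs, segs)
    cand = _truth_model(0.6, [(1, 0)] * 4, lengths)  # ploidy 1.0 < 1.2
    cand.mse_lr, cand.mse_maf = -1.0, -1.0  # force rule 1 past
    chosen, log = select_model(gibbs, [cand], segs)
    assert chosen is gibbs
    assert not log[-1]["rule2_ploidy_floor"]


def test_selection_rejects_near_pure_candidate_without_agreement():
    states = [(2, 1), (3, 1), (2, 0), (4, 1)]
    segs, _ = _toy_segments(0.6, states)
    lengths = [s.length for s in segs]
    gibbs = _truth_model(0.6, states, lengths)
    gibbs.source = "gibbs"
    gibbs.mse_lr, gibbs.mse_maf = score_model(gibbs, segs)
    cand = _truth_model(0.995, states, lengths)
    cand.mse_lr, cand.mse_maf = -1.0, -1.0
    chosen, log = select_model(gibbs, [cand], segs)
    assert chosen is gibbs
    assert not log[-1]["rule5_purity_cap"]
    # ... unless the independent near-purity heuristic agrees and the
    # candidate genuinely fits better
    cand2 = _truth_model(0.995, states, lengths)
    cand2.mse_lr, cand2.mse_maf = -1.0, -1.0
    chosen2, log2 = select_model(gibbs, [cand2], segs, high_purity_agrees=True)
    assert log2[-1]["rule5_purity_cap"]


def test_high_purity_check_on_simulated_specimens():
    from sgz.simdata import SegmentSpec

    loh = SimulationConfig(
        seed=2, purity=1.0,
        segments=[SegmentSpec(f"chr{i}", 60, C, 0) for i, C in
                  enumerate([1, 2, 1, 2], start=1)],
    )
    assert high_purity_check(select_het_snps(simulate_specimen(loh).snps)) is True
    mid = SimulationConfig(seed=3, purity=0.3)
    assert high_purity_check(select_het_snps(simulate_specimen(mid).snps)) is False
    assert high_purity_check(None) is False


def test_estimator_exposes_fitted_attributes(pipeline_mid):
    est = pipeline_mid["estimator"]
    assert 0.0 <= est.purity_ <= 1.0
    assert est.ploidy_ > 0
    assert est.source_ in ("gibbs", "grid")
    assert len(est.copy_number_) == len(pipeline_mid["segments"])
    assert all(
        0 <= m <= c // 2 for c, m in zip(est.copy_number_, est.minor_count_)
    )


def test_estimator_recovers_specimen_truth(specimen_mid, pipeline_mid):
    from sgz.pipeline import copy_number_accuracy

    model = pipeline_mid["model"]
    assert abs(model.purity - specimen_mid.truth["purity"]) <= 0.05
    acc = copy_number_accuracy(
        pipeline_mid["segments"], model, specimen_mid.truth["segments"]
    )
    assert acc >= 0.95
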