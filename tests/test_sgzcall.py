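"""The SGZ decision engine: binomial tests, decision rules, zygosity, gates."""

import numpy as np
import pytest
from scipy import stats

from sgz.sgzcall import (
    SgzClassifier,
    VariantObservation,
    basic_method_classify,
    classify_variant,
    classify_zygosity,
    two_tailed_binomial_p,
)
from tests.conftest import make_single_segment_model


def _variant(n, f, pos=500_000):
    return VariantObservation("chr1", pos, "A", "T", n, f)


# ---------------------------------------------------------------------------
# two-tailed binomial test


@pytest.mark.parametrize(
    "k,n,q,expected",
    [
        (5, 10, 0.5, 1.0),           # observation at the mode
        (0, 10, 0.5, 2.0 / 1024.0),  # both extreme tails, enumerated
        (10, 10, 1.0, 1.0),          # certain outcome
        (0, 10, 0.0, 1.0),
        (3, 10, 0.0, 0.0),
    ],
)
def test_two_tailed_binomial_values(k, n, q, expected):
    assert two_tailed_binomial_p(k, n, q) == pytest.approx(expected, rel=1e-12)


def test_two_tailed_matches_scipy_oracle():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(1, 60))
        k = int(rng.integers(0, n + 1))
        q = float(rng.uniform(0.02, 0.98))
        want = stats.binomtest(k, n, q).pvalue
        assert two_tailed_binomial_p(k, n, q) == pytest.approx(want, rel=1e-9)


# ---------------------------------------------------------------------------
# decision rules


def test_het_germline_called_germline():
    model, segs = make_single_segment_model(0.3, 2, 1)
    call = classify_variant(_variant(500, 0.5), model, segs)
    assert call.status == "germline"
    assert call.zygosity == "heterozygous"
    assert call.p_germline > 0.01 and call.p_somatic <= 0.01


def test_het_somatic_called_somatic():
    model, segs = make_single_segment_model(0.3, 2, 1)
    call = classify_variant(_variant(500, 0.15), model, segs)
    assert call.status == "somatic"
    assert call.zygosity == "heterozygous"


def test_deeply_depressed_af_called_subclonal():
    model, segs = make_single_segment_model(0.5, 2, 1)
    call = classify_variant(_variant(1000, 0.05), model, segs)
    assert call.status == "subclonal_somatic"
    assert call.zygosity == "subclonal"


def test_cn3_loh_33_percent_is_ambiguous():
    """The worked degeneracy: f=1/3 in a CN-3 LOH segment at purity 0.25 is
    equally compatible with germline-not-in-tumor and somatic-homozygous."""
    model, segs = make_single_segment_model(0.25, 3, 0)
    call = classify_variant(_variant(1000, 1.0 / 3.0), model, segs)
    assert call.status == "ambiguous"
    assert call.reason == "compatible_with_both"
    assert call.af_germline == pytest.approx(call.af_somatic, abs=1e-9)


def test_germline_lost_from_tumor_is_not_in_tumor():
    model, segs = make_single_segment_model(0.4, 1, 0)
    f = (1 - 0.4) / (0.4 + 2 * 0.6)  # germline V=0 expectation
    call = classify_variant(_variant(800, f), model, segs)
    assert call.status == "germline"
    assert call.zygosity == "not_in_tumor"
    assert call.v_germline == 0


def test_homozygous_somatic_zygosity():
    model, segs = make_single_segment_model(0.6, 2, 0)
    f = 0.6 * 2 / (0.6 * 2 + 0.8)  # somatic V=C expectation
    call = classify_variant(_variant(800, f), model, segs)
    assert call.status == "somatic"
    assert call.zygosity == "homozygous"


@pytest.mark.parametrize(
    "V,C,expected",
    [(3, 3, "homozygous"), (1, 2, "heterozygous"), (0, 2, "not_in_tumor")],
)
def test_classify_zygosity(V, C, expected):
    assert classify_zygosity(V, C) == expected


# ---------------------------------------------------------------------------
# gates and no-call taxonomy


def test_high_purity_gate_blocks_all_calls():
    model, segs = make_single_segment_model(0.97, 2, 1)
    call = classify_variant(_variant(800, 0.5), model, segs)
    assert call.status == "ambiguous" and call.reason == "high_purity"


def test_no_subclonal_calls_at_or_below_20_percent_purity():
    for purity in (0.10, 0.15, 0.20):
        model, segs = make_single_segment_model(purity, 2, 1)
        for f in np.linspace(0.0, 0.3, 16):
            call = classify_variant(_variant(1000, float(f)), model, segs)
            assert call.status != "subclonal_somatic"


def test_zygosity_reported_only_at_20_percent_purity():
    model, segs = make_single_segment_model(0.15, 2, 1)
    call = classify_variant(_variant(800, 0.5), model, segs)
    assert call.status == "germline"
    assert call.zygosity == "NA"


def test_model_misfit_segment_is_no_called():
    model, segs = make_single_segment_model(0.5, 2, 1)
    segs[0].median_lr += 10 * segs[0].sd_lr
    call = classify_variant(_variant(800, 0.5), model, segs)
    assert call.status == "ambiguous" and call.reason == "model_misfit"


def test_variant_off_modeled_chromosomes_is_no_called():
    model, segs = make_single_segment_model(0.5, 2, 1)
    v = VariantObservation("chrX", 100, "A", "T", 800, 0.5)
    call = classify_variant(v, model, segs)
    assert call.status == "ambiguous" and call.reason == "model_misfit"


def test_af_outside_both_expectations_is_no_called():
    model, segs = make_single_segment_model(0.5, 2, 1)
    call = classify_variant(_variant(1000, 0.99), model, segs)
    assert call.status == "ambiguous" and call.reason == "outside_both"


def test_every_ambiguous_call_has_exactly_one_reason(pipeline_mid):
    df = pipeline_mid["calls_df"]
    amb = df[df["status"] == "ambiguous"]
    ok = df[df["status"] != "ambiguous"]
    assert (amb["reason"] != "none").all()
    assert (ok["reason"] == "none").all()
    assert set(df["status"]) <= {"somatic", "germline", "subclonal_somatic", "ambiguous"}


# ---------------------------------------------------------------------------
# basic AF-only comparator


@pytest.mark.parametrize(
    "f,expected",
    [(0.50, "germline"), (0.25, "somatic"), (0.95, "germline"),
     (0.42, "germline"), (0.05, "somatic")],
)
def test_basic_method(f, expected):
    assert basic_method_classify(f) == expected


def test_basic_method_always_calls(pipeline_mid, specimen_mid):
    clf = SgzClassifier(basic_method=True).fit(pipeline_mid["model"])
    from sgz.sgzcall import variants_from_frame

    calls = clf.predict_calls(variants_from_frame(specimen_mid.variants, zero_based=True))
    assert all(c.status in ("germline", "somatic") for c in calls)


# ---------------------------------------------------------------------------
# model-equivalence property


def _doubled(purity, C, M):
    """The genome-doubled equivalent model: C->2C, M->2M, odds halved."""
    return purity / (2.0 - purity), 2 * C, 2 * M


def test_expectation_equivalent_models_give_identical_calls():
    """Models with identical expected-AF candidate sets (the doubling
    family) must classify every observation identically."""
    rng = np.random.default_rng(17)
    for _ in range(100):
        p = float(rng.uniform(0.35, 0.94))
        C = int(rng.integers(1, 6))
        M = int(rng.integers(0, C // 2 + 1))
        p2, C2, M2 = _doubled(p, C, M)
        m1, s1 = make_single_segment_model(p, C, M)
        m2, s2 = make_single_segment_model(p2, C2, M2)
        n = int(rng.integers(100, 1500))
        f = float(rng.uniform(0.0, 1.0))
        a = classify_variant(_variant(n, f), m1, s1)
        b = classify_variant(_variant(n, f), m2, s2)
        assert (a.status, a.zygosity, a.reason) == (b.status, b.zygosity, b.reason)
        assert a.p_germline == pytest.approx(b.p_germline, rel=1e-9)
        assert a.p_somatic == pytest.approx(b.p_somatic, rel=1e-9)
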