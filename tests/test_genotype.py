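"""Genotype-model checks: class probabilities, likelihood oracle agreement,
posterior behavior, calibration gates and noise estimation."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biallelic import (
    ModelConfig,
    PileupColumn,
    SimScenario,
    class_probabilities,
    classify_counts,
    classify_pileup,
    classify_site,
    estimate_error_rate,
    genotype_log_likelihoods,
    simulate_pileup,
    site_frequency_table,
)
from biallelic.pileup_io import TranscriptPileup

UNIFORM = ModelConfig(min_depth=1, posterior_threshold=0.51)


def brute_force_logpmf(k: int, d: int, p: float) -> float:
    """Independent binomial log-pmf from the factorial definition."""
    if p == 0.0:
        return 0.0 if k == 0 else -math.inf
    if p == 1.0:
        return 0.0 if k == d else -math.inf
    log_comb = math.lgamma(d + 1) - math.lgamma(k + 1) - math.lgamma(d - k + 1)
    return log_comb + k * math.log(p) + (d - k) * math.log(1 - p)


def test_class_probabilities_reduce_to_printed_model_at_zero_error():
    assert np.allclose(class_probabilities(0.0), [1.0, 0.5, 0.0])


def test_class_probabilities_reject_degenerate_error():
    # at eps >= 0.75 the hom-ref and het classes swap order
    with pytest.raises(ValueError, match="0.75"):
        class_probabilities(0.75)


def test_pure_reference_column_forced_hom_ref():
    """d=100, k=100, eps=0: hom_ref log-likelihood is exactly 0 and the het
    alternative (0.5^100) cannot win."""
    calls, ll, post = classify_counts([100], [100], 0.0, UNIFORM)
    assert calls[0] == "hom_ref"
    assert ll[0, 0] == 0.0
    assert np.isclose(ll[0, 1], 100 * math.log(0.5))
    assert ll[0, 2] == -np.inf


def test_balanced_column_called_het_with_bruteforce_posteriors():
    d, k, e = 100, 50, 0.01
    cfg = ModelConfig(min_depth=20, posterior_threshold=0.95)
    calls, ll, post = classify_counts([k], [d], e, cfg)
    assert calls[0] == "het"
    probs = class_probabilities(e)
    expected_ll = np.array([brute_force_logpmf(k, d, p) for p in probs])
    assert np.allclose(ll[0], expected_ll, atol=1e-9)
    w = np.exp(expected_ll - expected_ll.max()) * np.asarray(cfg.priors)
    assert np.allclose(post[0], w / w.sum(), atol=1e-12)


def test_depth_gate_forces_no_call():
    cfg = ModelConfig(min_depth=20)
    calls, _, _ = classify_counts([10, 0], [10, 10], 0.0, cfg)
    assert list(calls) == ["no_call", "no_call"]


def test_ref_count_exceeding_depth_rejected():
    with pytest.raises(ValueError, match="exceeds depth"):
        genotype_log_likelihoods([5], [4], 0.0)


def test_posterior_normalization():
    k = np.arange(0, 61)
    _, _, post = classify_counts(k, np.full_like(k, 60), 0.01, UNIFORM)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    d=st.integers(1, 200),
    frac=st.floats(0, 1),
)
def test_label_symmetry_at_zero_error(d, frac):
    """With eps=0 the collapsed ref-vs-non-ref model is exactly symmetric:
    exchanging reference and pooled alternative (k -> d-k with mirrored
    priors) swaps the hom posteriors and fixes the het posterior.  With
    eps > 0 the epsilon/3 split of the hom-alt class breaks the symmetry
    (the non-reference pool contains two non-alt bases), so exactness is
    only claimed at zero error."""
    e = 0.0
    k = int(round(frac * d))
    cfg = ModelConfig(priors=(0.5, 0.3, 0.2), min_depth=1, posterior_threshold=0.51)
    mirrored = ModelConfig(priors=(0.2, 0.3, 0.5), min_depth=1, posterior_threshold=0.51)
    _, _, post = classify_counts([k], [d], e, cfg)
    _, _, post_m = classify_counts([d - k], [d], e, mirrored)
    assert np.allclose(post[0], post_m[0, ::-1], atol=1e-10)


def test_calls_partition_counts_into_contiguous_bands():
    """For fixed depth and error rate with uniform priors, the call as a
    function of k runs hom_alt | het | hom_ref in contiguous bands."""
    d, e = 60, 0.01
    k = np.arange(d + 1)
    calls, _, _ = classify_counts(k, np.full_like(k, d), e, ModelConfig(min_depth=1, posterior_threshold=0.51))
    order = {"hom_alt": 0, "het": 1, "hom_ref": 2}
    ranks = [order[c] for c in calls if c != "no_call"]
    assert ranks == sorted(ranks)
    assert set(calls) >= {"hom_alt", "het", "hom_ref"}


def _pileup_from_counts(rows, gene="NEG"):
    positions = np.arange(1, len(rows) + 1)
    refs = np.array(["A"] * len(rows))
    counts = np.zeros((len(rows), 4), dtype=np.int64)
    for i, (ref_n, alt_n) in enumerate(rows):
        counts[i, 0] = ref_n  # A is reference
        counts[i, 2] = alt_n  # G pools the mismatches
    return TranscriptPileup("s1", gene, positions, refs, counts)


class TestErrorEstimation:
    def test_zero_mismatches_gives_zero(self):
        tp = _pileup_from_counts([(100, 0), (50, 0)])
        est = estimate_error_rate([tp])
        assert est.error_rate == 0.0
        assert est.pooled_depth == 150

    def test_pooled_ratio_by_definition(self):
        # pooled depth 10,000 with 100 non-reference bases
        tp = _pileup_from_counts([(9900 - 4950, 50), (4950, 50)])
        est = estimate_error_rate([tp])
        assert est.error_rate == pytest.approx(0.01)
        assert est.pooled_depth == 10_000
        assert est.n_positions_excluded == 0

    def test_outlier_position_excluded_and_ratio_recomputed(self):
        """A 50% non-reference position (a plausible true variant) is dropped
        and eps re-pooled over the remainder, matching the hand-computed ratio."""
        tp = _pileup_from_counts([(4950, 50), (4950, 50), (500, 500)])
        est = estimate_error_rate([tp], outlier_fraction=0.2)
        assert est.n_positions_excluded == 1
        assert est.excluded_positions == (("NEG", 3),)
        assert est.pooled_depth == 10_000
        assert est.error_rate == pytest.approx(100 / 10_000)

    def test_no_usable_columns_raises(self):
        with pytest.raises(ValueError, match="no pileup columns"):
            estimate_error_rate([])

    def test_recovery_on_hemizygous_simulation(self):
        """|eps_hat - eps| <= 3 sd on a noise-only (hemizygous) simulation."""
        eps = 0.01
        scn = SimScenario(gene="TMLHE", transcript_length=200, divergent_sites=(),
                          error_rate=eps, depth=50, n_samples=20, seed=9)
        pileups, _ = simulate_pileup(scn)
        est = estimate_error_rate(pileups)
        se = math.sqrt(eps * (1 - eps) / est.pooled_depth)
        assert abs(est.error_rate - eps) <= 3 * se


def test_site_frequency_table_arithmetic():
    tp = TranscriptPileup(
        "s1", "g",
        positions=[1, 2],
        ref_bases=["A", "C"],
        counts=np.array([[5, 0, 0, 0], [0, 3, 3, 0]]),
    )
    table = site_frequency_table([tp]).set_index("pos")
    assert table.loc[1, "nonref_fraction"] == 0.0
    assert table.loc[2, "ref_fraction"] == pytest.approx(0.5)
    assert table.loc[2, "fG"] == pytest.approx(0.5)


def test_classify_site_matches_vectorized_path():
    col = PileupColumn(gene="g", pos=7, ref_base="A", counts={"A": 30, "C": 28, "G": 1, "T": 1})
    call = classify_site(col, UNIFORM, error_rate=0.01)
    calls, ll, post = classify_counts([30], [60], 0.01, UNIFORM)
    assert call.call == calls[0]
    assert np.allclose(call.log_likelihoods, ll[0])
    assert np.allclose(call.posteriors, post[0])
    assert call.depth_used == 60


def test_simulated_het_sites_recovered(het_scenario):
    """End to end on the balanced-het scenario: divergent sites come out het,
    background hom_ref, at depth 80 and eps=0.01."""
    pileups, _ = simulate_pileup(het_scenario)
    for tp in pileups:
        report = classify_pileup(tp, ModelConfig(), error_rate=0.01)
        div = report["pos"].isin(het_scenario.divergent_sites)
        assert (report.loc[div, "call"] == "het").all()
        assert (report.loc[~div, "call"] == "hom_ref").all()
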