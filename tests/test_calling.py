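"""Genotype caller: likelihood oracle, EM frequency recovery, filters,
naive caller rules and dual-caller set algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploscan.calling import (
    call_pileups,
    call_site,
    classify_caller_sets,
    estimate_cohort_af,
    genotype_likelihoods,
    hard_filter,
    naive_caller,
    naive_call_matrix,
    SiteCallStats,
    _log10_lik,
)
from haploscan.simulate import sample_cohort, simulate_haplotype_pool
from conftest import pileups_from_truth


def oracle_log10_lik(ref_count: int, alt_count: int, eps: float) -> list[float]:
    """Independent per-read brute force: multiply read probabilities one by one."""
    p_ref = {0: 1 - eps, 1: 0.5 * (1 - eps) + 0.5 * eps / 3, 2: eps / 3}
    out = []
    for g in (0, 1, 2):
        terms = [math.log10(p_ref[g])] * ref_count
        p_alt = p_ref[2 - g]
        terms += [math.log10(p_alt)] * alt_count
        out.append(math.fsum(terms))
    return out


def test_likelihood_matches_bruteforce_oracle_to_1e9():
    """Closed-form likelihoods equal per-read enumeration for all depths <= 12."""
    eps = 0.01
    for ref in range(13):
        for alt in range(13 - ref):
            if ref + alt == 0:
                continue
            got = genotype_likelihoods(ref, alt, eps).log10_lik
            want = oracle_log10_lik(ref, alt, eps)
            assert np.allclose(got, want, atol=1e-9)


def test_frozen_homref_example():
    """(10, 0, eps=0.01): oracle-computed values, PL normalised, GQ = 2nd PL."""
    gl = genotype_likelihoods(10, 0, 0.01)
    want = oracle_log10_lik(10, 0, 0.01)
    assert np.allclose(gl.log10_lik, want, atol=1e-9)
    assert np.allclose(gl.log10_lik, [-0.0436480540245009, -3.039349863073884, -24.771212547196626], atol=1e-9)
    assert gl.pl == (0, 30, 247)
    assert gl.gq == 30


def test_balanced_het_has_pl_zero_at_het():
    gl = genotype_likelihoods(5, 5, 0.01)
    assert gl.pl[1] == 0
    assert gl.pl[0] == gl.pl[2] > 0


def test_no_data_is_missing_with_gq_zero():
    gl = genotype_likelihoods(0, 0, 0.01)
    assert gl.missing and gl.gq == 0 and gl.pl == (0, 0, 0)


def test_pl_normalisation_and_gq_cap():
    gl = genotype_likelihoods(200, 0, 0.01)
    assert min(gl.pl) == 0
    assert gl.gq == 99  # capped


@given(st.integers(0, 40), st.integers(0, 40))
@settings(max_examples=200, derandomize=True, deadline=None)
def test_pl_invariants_property(ref, alt):
    if ref + alt == 0:
        return
    gl = genotype_likelihoods(ref, alt, 0.01)
    assert min(gl.pl) == 0
    assert gl.gq == sorted(gl.pl)[1] or (gl.gq == 99 and sorted(gl.pl)[1] >= 99)


def test_af_em_boundary_fixed_points():
    l10 = _log10_lik(np.array([30, 30, 30]), np.array([0, 0, 0]), 0.01)
    assert estimate_cohort_af(l10) < 1e-4
    l10 = _log10_lik(np.array([40, 0]), np.array([0, 40]), 1e-4)
    assert abs(estimate_cohort_af(l10) - 0.5) < 1e-3


def test_af_em_all_missing_raises():
    l10 = np.zeros((3, 3))
    with pytest.raises(ValueError, match="missing"):
        estimate_cohort_af(l10, has_data=np.zeros(3, dtype=bool))


def test_af_em_parameter_recovery():
    """af_hat recovers a true frequency of 0.3 within 3 SE over replicates."""
    rng = np.random.default_rng(5)
    true_af, n, depth = 0.3, 100, 30
    ests = []
    for _ in range(40):
        geno = rng.binomial(2, true_af, size=n)
        alt = rng.binomial(depth, np.where(geno == 1, 0.5, geno / 2) * 0.99 + 0.00333)
        l10 = _log10_lik(depth - alt, alt, 0.01)
        ests.append(estimate_cohort_af(l10))
    ests = np.asarray(ests)
    se = ests.std(ddof=1) / np.sqrt(ests.size)
    assert abs(ests.mean() - true_af) < 3 * se + 0.01


def test_call_site_no_variant_when_af_zero():
    l10 = _log10_lik(np.array([20, 20]), np.array([0, 0]), 0.01)
    calls, post, stats = call_site(l10, af_hat=0.0, depths=np.array([20, 20]))
    assert np.all(calls == 0)
    assert stats.qual == 0.0


def test_call_site_single_het_qd():
    l10 = _log10_lik(np.array([10, 20]), np.array([10, 0]), 0.01)
    calls, _, stats = call_site(l10, af_hat=0.05, depths=np.array([20, 20]))
    assert calls.tolist() == [1, 0]
    assert stats.qual > 0
    assert stats.qd == pytest.approx(stats.qual / 20)


def test_hard_filter_boundaries():
    ok, reasons = hard_filter(SiteCallStats(0, 0.1, 50, 4.9, 0, 0))
    assert not ok and reasons == ("LowQD",)
    ok, _ = hard_filter(SiteCallStats(0, 0.1, 50, 5.0, 0, 0))
    assert ok  # boundary passes: strictly-less fails
    ok, reasons = hard_filter(SiteCallStats(0, 0.1, 50, 9.0, 61.0, 0))
    assert not ok and "HighFS" in reasons
    ok, reasons = hard_filter(SiteCallStats(0, 0.1, 50, 9.0, 0, -8.5))
    assert not ok and "LowRPRS" in reasons
    # alignment-level thresholds are accepted but inert
    ok, _ = hard_filter(SiteCallStats(0, 0.1, 50, 9.0, 0, 0), {"MQ": 40.0, "HaplotypeScore": 13.0})
    assert ok


@pytest.mark.parametrize(
    "ref,alt,expected",
    [(20, 0, 0), (10, 10, 1), (1, 19, 2), (0, 0, -1), (18, 2, 0)],
)
def test_naive_caller_rules(ref, alt, expected):
    assert naive_caller(ref, alt) == expected


def test_caller_set_codes_toy_example():
    codes, summary = classify_caller_sets({1, 2}, {2, 3}, {1})
    assert codes == {1: "3b", 2: "1", 3: "2"}
    assert summary["n_union"] == 3


def test_caller_set_inclusion_exclusion_random():
    rng = np.random.default_rng(0)
    for _ in range(50):
        universe = np.arange(60)
        a = set(rng.choice(universe, rng.integers(0, 40), replace=False).tolist())
        b = set(rng.choice(universe, rng.integers(0, 40), replace=False).tolist())
        fail = set(rng.choice(universe, 10, replace=False).tolist()) - b
        codes, summary = classify_caller_sets(a, b, fail)
        assert summary["n_union"] == len(a | b)
        assert summary["n_intersection"] == len(a & b)
        # brute-force re-derivation of every code
        for p, c in codes.items():
            want = (
                "1" if p in a and p in b
                else "2" if p in b
                else "3b" if p in fail
                else "3a"
            )
            assert c == want


def test_caller_sets_reject_pass_fail_overlap():
    with pytest.raises(ValueError):
        classify_caller_sets({1}, {2}, {2})


def test_empty_caller_sets():
    codes, summary = classify_caller_sets(set(), set(), set())
    assert codes == {} and summary["n_union"] == 0


def test_high_depth_accuracy_above_99(region):
    """Per-genotype accuracy > 0.99 at depth 20, eps = 0.01 on synthetic truth."""
    pool = simulate_haplotype_pool(region, n_founders=24, theta_sim=5e-4, seed=31)
    cohort = sample_cohort(pool, n_cases=60, n_controls=0, n_reference=0, seed=32)
    frame = pileups_from_truth(cohort, depth=20, epsilon=0.01, seed=33)
    callset = call_pileups(frame, epsilon=0.01)
    truth = cohort.genotype_matrix("case")
    keep = np.isin(pool.positions, callset.positions)
    assert keep.all()
    acc = (callset.genotypes == truth).mean()
    assert acc > 0.99


def test_noiseless_calls_recover_truth_exactly(region):
    """With eps -> 0 in the reads and depth >= 10, calls equal truth."""
    pool = simulate_haplotype_pool(region, n_founders=16, theta_sim=4e-4, seed=41)
    cohort = sample_cohort(pool, n_cases=20, n_controls=0, n_reference=0, seed=42)
    frame = pileups_from_truth(cohort, depth=12, epsilon=0.0, seed=43)
    callset = call_pileups(frame, epsilon=0.01)
    truth = cohort.genotype_matrix("case")
    assert np.array_equal(callset.genotypes, truth)


def test_naive_matrix_agrees_with_scalar_rule(region):
    pool = simulate_haplotype_pool(region, n_founders=16, theta_sim=4e-4, seed=41)
    cohort = sample_cohort(pool, n_cases=6, n_controls=0, n_reference=0, seed=42)
    frame = pileups_from_truth(cohort, depth=15, epsilon=0.01, seed=44)
    positions, samples, geno = naive_call_matrix(frame)
    lookup = {(r.sample_id, r.pos): (r.ref_count, r.alt_count) for r in frame.itertuples()}
    for j, p in enumerate(positions):
        for i, s in enumerate(samples):
            ref, alt = lookup[(s, p)]
            assert geno[j, i] == naive_caller(ref, alt)
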