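"""Haplotype classification, diversity, exclusivity, LD and phasing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploscan.haplotypes import (
    ND,
    OTHER,
    PROT,
    RISK,
    classify_chromosome,
    classify_chromosomes,
    diversity_by_class,
    exclusivity_code,
    harmonic_number,
    ld_r2,
    phase_em,
    segregation_scan,
    tagged_by,
    watterson_theta,
)
from haploscan.region import default_region
from haploscan.simulate import sample_cohort, simulate_haplotype_pool, simulate_stratified_pool

TAGS = np.arange(6)
RISK_PAT = np.ones(6, dtype=int)
PROT_PAT = np.zeros(6, dtype=int)


def test_classification_definitions():
    assert classify_chromosome(RISK_PAT, TAGS, RISK_PAT, PROT_PAT) == RISK
    assert classify_chromosome(PROT_PAT, TAGS, RISK_PAT, PROT_PAT) == PROT
    five_of_six = RISK_PAT.copy()
    five_of_six[3] = 0
    assert classify_chromosome(five_of_six, TAGS, RISK_PAT, PROT_PAT) == OTHER
    missing = RISK_PAT.copy()
    missing[0] = -1
    assert classify_chromosome(missing, TAGS, RISK_PAT, PROT_PAT) == ND


def test_classification_is_a_partition():
    """Every tag-complete chromosome receives exactly one of the 3 labels."""
    for bits in itertools.product((0, 1), repeat=6):
        label = classify_chromosome(np.array(bits), TAGS, RISK_PAT, PROT_PAT)
        assert label in (RISK, PROT, OTHER)


def test_cohort_class_counts_match_configured_fractions(region):
    """Class counts over 94 chromosomes stay within multinomial error of
    the configured (0.42, 0.14, 0.44) frequencies."""
    pool = simulate_haplotype_pool(
        region, n_founders=30, theta_sim=3e-4, seed=51, class_fractions=(0.42, 0.14, 0.44)
    )
    counts = {RISK: [], PROT: []}
    for rep in range(60):
        cohort = sample_cohort(pool, n_cases=47, n_controls=0, n_reference=0,
                               seed=900 + rep, case_class_or={})
        labels = cohort.chromosome_classes("case")
        counts[RISK].append(np.sum(labels == RISK))
        counts[PROT].append(np.sum(labels == PROT))
    f = pool.class_frequencies()
    for cls in (RISK, PROT):
        arr = np.asarray(counts[cls], dtype=float)
        se = arr.std(ddof=1) / np.sqrt(arr.size)
        assert abs(arr.mean() - 94 * f[cls]) < 3 * se + 1e-9


def test_watterson_arithmetic():
    assert watterson_theta(0, 10, 1000) == 0.0
    a9 = harmonic_number(10)
    assert a9 == pytest.approx(2.828968, abs=1e-6)
    assert watterson_theta(10, 10, 10_000) == pytest.approx(3.5349e-4, rel=1e-4)
    with pytest.raises(ValueError):
        watterson_theta(1, 1, 1000)


@pytest.mark.parametrize("n", [10, 40, 100])
def test_watterson_unbiased_on_coalescent_simulations(n):
    """Mean theta-hat over 200 replicates within 3 SE of the configured value."""
    region = default_region("test")
    theta = 5e-4
    ests = []
    for rep in range(200):
        pool = simulate_haplotype_pool(
            region, n_founders=n, theta_sim=theta, seed=3000 + rep
        )
        S = pool.n_sites - 6  # background (neutral) sites only
        ests.append(watterson_theta(S, n, region.length_bp))
    ests = np.asarray(ests)
    se = ests.std(ddof=1) / np.sqrt(ests.size)
    assert abs(ests.mean() - theta) < 3 * se


def test_diversity_by_class_degenerate_and_shared():
    haps = np.zeros((6, 4), dtype=int)
    labels = np.array([RISK, RISK, PROT, PROT, OTHER, OTHER], dtype=object)
    rep = diversity_by_class(haps, labels, 1000)
    assert all(v["theta"] == 0 for v in rep.per_class.values())

    # two classes sharing all variants: equal S, theta differs only via n
    haps = np.array([[0, 1], [1, 0], [0, 1], [1, 0], [0, 1], [1, 0]])
    labels = np.array([RISK, RISK, RISK, RISK, OTHER, OTHER], dtype=object)
    rep = diversity_by_class(haps, labels, 1000)
    assert rep.per_class[RISK]["S"] == rep.per_class[OTHER]["S"] == 2
    assert rep.per_class[RISK]["theta"] < rep.per_class[OTHER]["theta"]


def test_stratified_diversity_recovers_ordering(region):
    """Configured (low, low, high) per-class theta is recovered in the
    cohort estimates in >= 95% of replicate cohorts."""
    ok = 0
    n_rep = 50
    for rep in range(n_rep):
        pool = simulate_stratified_pool(
            region,
            founders_per_class=(20, 10, 20),
            theta_per_class=(3.5e-4, 3.7e-4, 8.4e-4),
            seed=5000 + rep,
            class_fractions=(0.42, 0.14, 0.44),
        )
        cohort = sample_cohort(pool, n_cases=47, n_controls=0, n_reference=0,
                               seed=6000 + rep, case_class_or={})
        haps = cohort.haplotype_matrix("case")
        labels = cohort.chromosome_classes("case")
        div = diversity_by_class(haps, labels, region.length_bp)
        if not {RISK, PROT, OTHER} <= set(div.per_class):
            continue
        t = {c: div.per_class[c]["theta"] for c in (RISK, PROT, OTHER)}
        ok += t[OTHER] > t[RISK] and t[OTHER] > t[PROT]
    assert ok >= 0.95 * n_rep


def _exclusivity_oracle(column, labels):
    """Brute force re-derivation of the exclusivity code definition."""
    known = column[column >= 0]
    f = known.mean() if known.size else 0.0
    if f in (0.0, 1.0):
        return ("0", "0")
    minor = 1 if f <= 0.5 else 0
    carriers = [lab for al, lab in zip(column, labels) if al == minor]
    if any(lab == ND for lab in carriers):
        return (ND, ND)
    out = []
    for cls in (RISK, PROT):
        inside = sum(lab == cls for lab in carriers)
        out.append("0" if inside == 0 else "2" if inside == len(carriers) else "1")
    return tuple(out)


def test_exclusivity_definitions():
    labels = np.array([RISK, RISK, PROT, OTHER, OTHER, OTHER], dtype=object)
    col = np.array([1, 1, 0, 0, 0, 0])
    assert exclusivity_code(col, labels) == ("2", "0")
    col = np.array([1, 0, 0, 1, 0, 0])
    assert exclusivity_code(col, labels) == ("1", "0")
    col = np.array([0, 0, 0, 0, 0, 0])
    assert exclusivity_code(col, labels) == ("0", "0")
    nd_labels = labels.copy()
    nd_labels[3] = ND
    assert exclusivity_code(np.array([1, 0, 0, 1, 0, 0]), nd_labels) == (ND, ND)


@given(
    st.lists(st.integers(0, 1), min_size=8, max_size=8),
    st.lists(st.sampled_from([RISK, PROT, OTHER, ND]), min_size=8, max_size=8),
)
@settings(max_examples=300, derandomize=True, deadline=None)
def test_exclusivity_matches_bruteforce_oracle(column, labels):
    column = np.array(column)
    labels = np.array(labels, dtype=object)
    assert exclusivity_code(column, labels) == _exclusivity_oracle(column, labels)


def test_segregation_scan_definition_and_order_invariance():
    labels = np.array([RISK, PROT, OTHER, OTHER, OTHER, OTHER], dtype=object)
    haps = np.array(
        [
            [1, 1, 0],
            [0, 1, 0],
            [1, 0, 1],
            [1, 0, 0],
            [1, 0, 0],
            [1, 0, 0],
        ]
    )
    # site 0: minor allele is 0 carried by PROT only -> prot-segregating
    # site 1: carriers RISK + PROT -> neither; site 2: OTHER only -> neither
    risk_seg, prot_seg = segregation_scan(haps, labels)
    assert risk_seg == [] and prot_seg == [0]
    perm = np.array([3, 1, 0, 5, 2, 4])
    risk2, prot2 = segregation_scan(haps[perm], labels[perm])
    assert (risk2, prot2) == (risk_seg, prot_seg)


def test_segregation_scan_risk_only_carrier():
    labels = np.array([RISK, OTHER, OTHER, OTHER, OTHER, OTHER, PROT], dtype=object)
    col = np.array([[1], [1], [0], [0], [0], [0], [0]])
    risk_seg, prot_seg = segregation_scan(col, labels)
    assert risk_seg == [0] and prot_seg == []


def test_ld_r2_worked_values():
    a = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    assert ld_r2(a, a) == pytest.approx(1.0)
    assert tagged_by(a, a)
    b = np.array([1, 1, 0, 0, 1, 1, 0, 0])
    assert ld_r2(a, b) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        ld_r2(a, np.zeros(8))


def test_ld_r2_independence_limit():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 2, 4000)
    b = rng.integers(0, 2, 4000)
    assert ld_r2(a, b) < 0.01


def test_phase_em_panel_resolves_double_het():
    """Two coupled sites: the panel {00, 11} forces the coupling phase."""
    genotypes = np.array([[0, 0], [2, 2]] + [[1, 1]] * 10)
    panel = np.array([[0, 0], [1, 1]])
    haps, uncertain = phase_em(genotypes, window_size=2, panel=panel)
    for i in range(2, 12):
        pair = {tuple(haps[2 * i]), tuple(haps[2 * i + 1])}
        assert pair == {(0, 0), (1, 1)}
    # exhaustive-enumeration check: coupling likelihood beats repulsion
    assert not uncertain[2:].any()


def test_phase_em_unphaseable_single_het_flagged():
    genotypes = np.array([[1, 0], [1, 0]])
    haps, uncertain = phase_em(genotypes, window_size=2)
    # genotype dosages are preserved either way
    assert np.array_equal(haps[0] + haps[1], genotypes[0])


def test_phase_em_recovers_truth_at_high_ld(region):
    """Common coupled haplotypes phase correctly without a panel."""
    pool = simulate_haplotype_pool(region, n_founders=8, theta_sim=4e-4, seed=71)
    cohort = sample_cohort(pool, n_cases=40, n_controls=0, n_reference=0, seed=72)
    geno = cohort.genotype_matrix("case")  # (S, n)
    haps, _ = phase_em(geno.T, window_size=4, panel=pool.haplotypes)
    truth = cohort.haplotype_matrix("case")
    # compare per-sample unordered chromosome pairs
    match = 0
    n = geno.shape[1]
    for i in range(n):
        got = {tuple(haps[2 * i]), tuple(haps[2 * i + 1])}
        want = {tuple(truth[2 * i]), tuple(truth[2 * i + 1])}
        match += got == want
    assert match / n > 0.8


def test_truth_passthrough_identity(cohort):
    """Phased truth used directly round-trips through classification."""
    haps = cohort.haplotype_matrix("case")
    pool = cohort.pool
    labels = classify_chromosomes(haps, pool.tag_idx, pool.risk_alleles, pool.prot_alleles)
    founders = cohort.chrom_founders[cohort.indices("case")].reshape(-1)
    assert np.array_equal(labels, pool.founder_class[founders])
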