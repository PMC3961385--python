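"""Synthetic generator: infinite-sites structure, cohort draws, pileups."""

import numpy as np
import pytest

from haploscan.haplotypes import OTHER, PROT, RISK, harmonic_number
from haploscan.region import default_region
from haploscan.simulate import (
    DepthModel,
    ErrorModel,
    TagSpec,
    default_tag_spec,
    sample_cohort,
    simulate_haplotype_pool,
    simulate_pileups,
    simulate_stratified_pool,
)


def test_zero_mutation_limit_gives_tag_sites_only(region):
    pool = simulate_haplotype_pool(region, n_founders=10, theta_sim=0.0, seed=3)
    assert pool.n_sites == 6
    assert np.array_equal(pool.tag_idx, np.arange(6))


def test_infinite_sites_unique_positions(pool):
    assert np.unique(pool.positions).size == pool.n_sites
    # every non-tag site is polymorphic among founders
    bg = np.setdiff1d(np.arange(pool.n_sites), pool.tag_idx)
    counts = pool.haplotypes[:, bg].sum(axis=0)
    assert np.all((counts > 0) & (counts < pool.n_founders))


def test_expected_segregating_sites_matches_closed_form():
    """Replicate mean of S agrees with E[S] = theta * L * a_n within 3 SE."""
    region = default_region("test")
    theta, n = 1e-4, 20
    S = []
    for rep in range(200):
        p = simulate_haplotype_pool(region, n_founders=n, theta_sim=theta, seed=1000 + rep)
        S.append(p.n_sites - 6)
    S = np.asarray(S, dtype=float)
    expected = theta * region.length_bp * harmonic_number(n)  # ~3.55
    se = S.std(ddof=1) / np.sqrt(S.size)
    assert abs(S.mean() - expected) < 3 * se + 1e-9


def test_pool_determinism(region):
    a = simulate_haplotype_pool(region, n_founders=12, theta_sim=5e-4, seed=7)
    b = simulate_haplotype_pool(region, n_founders=12, theta_sim=5e-4, seed=7)
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.founder_frequencies, b.founder_frequencies)


def test_tag_collision_rejected():
    with pytest.raises(ValueError, match="collide"):
        TagSpec(positions=(1, 1, 2, 3, 4, 5), risk_alleles=(1,) * 6, prot_alleles=(0,) * 6)


def test_every_founder_is_classifiable(pool):
    assert set(pool.founder_class) <= {RISK, PROT, OTHER}


def test_stratified_pool_classes_have_disjoint_background(region):
    pool = simulate_stratified_pool(
        region, founders_per_class=(6, 4, 6), theta_per_class=(3e-4, 3e-4, 9e-4), seed=5
    )
    assert set(pool.founder_class[:6]) == {RISK}
    assert set(pool.founder_class[6:10]) == {PROT}


def test_cohort_geometry_and_determinism(pool):
    cohort = sample_cohort(pool, n_cases=48, n_controls=0, n_reference=174, seed=2)
    assert cohort.haplotype_matrix("case").shape[0] == 96
    assert cohort.haplotype_matrix("reference").shape[0] == 348
    again = sample_cohort(pool, n_cases=48, n_controls=0, n_reference=174, seed=2)
    assert np.array_equal(cohort.chrom_founders, again.chrom_founders)


def test_degenerate_founder_frequencies_give_identical_chromosomes(region):
    local = simulate_haplotype_pool(region, n_founders=10, theta_sim=2e-4, seed=13)
    degenerate = local.founder_frequencies * 0
    degenerate[0] = 1.0
    local.founder_frequencies = degenerate
    cohort = sample_cohort(local, 5, 0, 5, seed=1, case_class_or={})
    assert np.all(cohort.chrom_founders == 0)


def test_embedded_class_shift_recovers_binomial_mean(region):
    """Case risk-chromosome count matches n*p under the shifted frequencies."""
    pool = simulate_haplotype_pool(region, n_founders=20, theta_sim=2e-4, seed=9)
    base = pool.class_frequencies()[RISK]
    target = 0.36
    odds_ratio = (target / (1 - target)) / (base / (1 - base))
    counts = []
    for rep in range(400):
        cohort = sample_cohort(
            pool, n_cases=48, n_controls=0, n_reference=0,
            seed=rep, case_class_or={RISK: odds_ratio},
        )
        counts.append(np.sum(cohort.chromosome_classes("case") == RISK))
    counts = np.asarray(counts, dtype=float)
    expected = 96 * target  # ~34.6
    se = counts.std(ddof=1) / np.sqrt(counts.size)
    assert abs(counts.mean() - expected) < 3 * se + 1e-9


def test_zero_depth_means_empty_pileups(region, pool):
    cohort = sample_cohort(pool, 3, 0, 0, seed=4)
    depth = DepthModel(per_amplicon_mean=(0.0,) * 8, sample_scale_dispersion=0, site_dispersion=0)
    ps = simulate_pileups(cohort, region, depth, ErrorModel(), seed=0)
    assert ps.frame.empty


def test_noiseless_homref_pileup_is_pure_reference(region):
    pool = simulate_haplotype_pool(region, n_founders=10, theta_sim=0.0, seed=3)
    prot_founder = int(np.flatnonzero(pool.founder_class == PROT)[0])
    cohort = sample_cohort(pool, 2, 0, 0, seed=1, case_class_or={})
    cohort.chrom_founders[:] = prot_founder  # all-ref at every site
    depth = DepthModel(per_amplicon_mean=(30.0,) * 8, sample_scale_dispersion=0, site_dispersion=0)
    error = ErrorModel(epsilon_base=1e-12, epsilon_homopolymer=1e-12)
    ps = simulate_pileups(cohort, region, depth, error, seed=5)
    assert (ps.frame["alt_count"] == 0).all()
    assert (ps.frame["other_count"] == 0).all()
    # depth 30 Poisson mean: roughly 30 reads, never in the declared gap
    gap = region.gaps[0]
    assert not ((ps.frame["pos"] >= gap.start) & (ps.frame["pos"] < gap.end)).any()


def test_error_rate_recovered_from_homref_reads(region):
    """Non-reference read fraction matches epsilon on hom-ref truth."""
    pool = simulate_haplotype_pool(region, n_founders=10, theta_sim=0.0, seed=3)
    prot_founder = int(np.flatnonzero(pool.founder_class == PROT)[0])
    cohort = sample_cohort(pool, 4, 0, 0, seed=1, case_class_or={})
    cohort.chrom_founders[:] = prot_founder
    depth = DepthModel(per_amplicon_mean=(30.0,) * 8, sample_scale_dispersion=0, site_dispersion=0)
    error = ErrorModel(epsilon_base=0.01, epsilon_homopolymer=0.01)
    ps = simulate_pileups(cohort, region, depth, error, seed=6)
    nonref = (ps.frame["alt_count"] + ps.frame["other_count"]).sum()
    # emitted rows omit pure-reference site-samples, so measure the error
    # rate against the full read budget: 4 samples x covered sites x depth 30
    n_reads = 4 * sum(len(iv) for iv in region.amplicons) * 30
    frac = nonref / n_reads
    se = np.sqrt(0.01 * 0.99 / n_reads)
    assert abs(frac - 0.01) < 4 * se


def test_allelic_bias_skews_het_reads(region):
    pool = simulate_haplotype_pool(region, n_founders=10, theta_sim=0.0, seed=3)
    risk_founder = int(np.flatnonzero(pool.founder_class == RISK)[0])
    prot_founder = int(np.flatnonzero(pool.founder_class == PROT)[0])
    cohort = sample_cohort(pool, 6, 0, 0, seed=1, case_class_or={})
    cohort.chrom_founders[:, 0] = risk_founder
    cohort.chrom_founders[:, 1] = prot_founder  # het at every tag site
    site = int(pool.positions[0])
    depth = DepthModel(per_amplicon_mean=(200.0,) * 8, sample_scale_dispersion=0, site_dispersion=0)
    error = ErrorModel(epsilon_base=1e-9, epsilon_homopolymer=1e-9,
                       allelic_bias_sites={site: 0.1})
    ps = simulate_pileups(cohort, region, depth, error, seed=8)
    rows = ps.frame[ps.frame["pos"] == site]
    frac = rows["alt_count"].sum() / (rows["alt_count"] + rows["ref_count"]).sum()
    assert abs(frac - 0.1) < 0.03


def test_seeded_truth_bundle_is_byte_identical(tmp_path, region, pool):
    from haploscan.simulate import emit_truth

    cohort = sample_cohort(pool, 4, 0, 8, seed=3)
    p1 = emit_truth(cohort, region, tmp_path / "a", seed=9)
    p2 = emit_truth(cohort, region, tmp_path / "b", seed=9)
    for key in p1:
        assert (tmp_path / "a" / p1[key].name).read_bytes() == (tmp_path / "b" / p2[key].name).read_bytes()


def test_truth_vcf_dimensions(tmp_path, region):
    from haploscan import io as hio
    from haploscan.simulate import emit_truth

    pool = simulate_haplotype_pool(region, n_founders=8, theta_sim=2e-4, seed=21)
    cohort = sample_cohort(pool, 2, 0, 4, seed=3)
    paths = emit_truth(cohort, region, tmp_path, seed=1)
    truth = hio.read_vcf(paths["truth_vcf"])
    assert len(truth.sample_ids) == 2
    assert truth.positions.size == pool.n_sites
    assert truth.phased


def test_zero_overlap_track_config(tmp_path, region, pool):
    from haploscan import io as hio
    from haploscan.annotate import AnnotationTrack, overlap_annotate
    from haploscan.simulate import TrackConfig, emit_truth

    cohort = sample_cohort(pool, 2, 0, 4, seed=3)
    cfgzero = TrackConfig(dhsp_fraction=0, enhancer_fraction=0,
                          conserved_in_dhsp=0, conserved_outside=0)
    paths = emit_truth(cohort, region, tmp_path, seed=1, track_config=cfgzero)
    tracks = {
        "dhsp": AnnotationTrack("dhsp", hio.read_bed(paths["dhsp_bed"])),
        "enhancer": AnnotationTrack("enhancer", hio.read_bed(paths["enhancer_bed"])),
        "conserved": AnnotationTrack("conserved", hio.read_bed(paths["conserved_bed"])),
    }
    annos = overlap_annotate([int(p) for p in pool.positions], tracks)
    assert all(not a.in_dhsp and not a.in_enhancer and a.gerp_score is None for a in annos)


def test_tag_sites_are_catalogued_known(tmp_path, region, pool):
    from haploscan import io as hio
    from haploscan.frequencies import novelty_flag
    from haploscan.simulate import emit_truth

    cohort = sample_cohort(pool, 4, 0, 20, seed=3)
    paths = emit_truth(cohort, region, tmp_path, seed=1)
    catalogue = hio.read_catalogue(paths["catalogue"])
    for j in pool.tag_idx:
        assert novelty_flag(int(pool.positions[j]), catalogue) == "known"
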