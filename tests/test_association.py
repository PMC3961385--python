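"""Association statistics: OR/CI arithmetic, QC ordering, Bonferroni,
validation summary and parameter recovery on embedded effects."""

import numpy as np
import pytest

from haploscan.association import (
    allelic_assoc,
    bonferroni,
    qc_filter,
    validation_summary,
)
from haploscan.haplotypes import RISK
from haploscan.region import default_region
from haploscan.simulate import sample_cohort, simulate_haplotype_pool


def test_or_is_cross_product_ratio_and_ci_brackets():
    res = allelic_assoc(178, 242, 163, 157)
    assert res.or_hat == pytest.approx((178 * 157) / (242 * 163), rel=1e-12)
    assert res.ci95[0] < res.or_hat < res.ci95[1]


def test_printed_association_rows_reproduced():
    """Frequencies 0.423/0.509 and 0.459/0.381 at n = 210/160 individuals."""
    res = allelic_assoc(round(0.423 * 420), 420 - round(0.423 * 420),
                        round(0.509 * 320), 320 - round(0.509 * 320))
    assert round(res.or_hat, 2) == 0.71
    assert (round(res.ci95[0], 2), round(res.ci95[1], 2)) == (0.53, 0.95)
    assert res.p < 0.05
    res = allelic_assoc(round(0.459 * 420), 420 - round(0.459 * 420),
                        round(0.381 * 320), 320 - round(0.381 * 320))
    assert round(res.or_hat, 2) == 1.38


def test_null_table():
    res = allelic_assoc(10, 10, 10, 10)
    assert res.or_hat == 1.0 and res.p == 1.0


def test_label_swap_inverts_or_and_keeps_p():
    r1 = allelic_assoc(30, 70, 20, 80)
    r2 = allelic_assoc(20, 80, 30, 70)
    assert r2.or_hat == pytest.approx(1 / r1.or_hat, rel=1e-12)
    assert r2.p == pytest.approx(r1.p, rel=1e-12)


def test_zero_cell_gets_haldane_flag():
    res = allelic_assoc(4, 426, 0, 330)
    assert res.haldane
    assert res.or_hat > 0 and np.isfinite(res.ci95[1])
    # chi-square still computed from the raw counts
    assert res.chisq == pytest.approx(3.086, abs=5e-3)


def test_qc_sample_then_variant_order():
    # sample 2 misses 2/10 sites (20% > 10%) and is removed first; variant
    # MAFs are recomputed on the remaining samples
    rng = np.random.default_rng(0)
    geno = rng.integers(0, 2, size=(10, 6))
    geno[:, 5] = 1
    geno[0, 2] = -1
    geno[1, 2] = -1
    # variant 9: alt only in the to-be-removed sample -> MAF 0 after removal
    geno[9] = 0
    geno[9, 2] = 1
    ids = [f"s{i}" for i in range(6)]
    report, filtered, kept_pos, kept_ids = qc_filter(geno, ids, np.arange(10))
    assert report.excluded_samples == ["s2"]
    assert 9 in report.excluded_variants
    assert "s2" not in kept_ids


def test_qc_one_missing_of_ten_sites_kept():
    geno = np.ones((10, 2), dtype=int)
    geno[0, 0] = -1  # 10% missing == threshold, not above -> kept
    report, _, _, kept = qc_filter(geno, ["a", "b"], np.arange(10), min_maf=0.0)
    assert report.excluded_samples == []


def test_qc_all_removed_aborts():
    geno = np.full((4, 2), -1)
    with pytest.raises(ValueError, match="removed all samples"):
        qc_filter(geno, ["a", "b"], np.arange(4))


def test_maf_boundary_0049_removed():
    # 1000 chromosomes, 49 alt -> MAF 0.049 < 0.05 removed
    geno = np.zeros((1, 500), dtype=int)
    geno[0, :49] = 1
    report, filtered, _, _ = qc_filter(geno, [f"s{i}" for i in range(500)], np.array([0]))
    assert report.excluded_variants == [0]


def test_bonferroni_arithmetic():
    assert bonferroni([0.019])[0] == pytest.approx(0.209)
    assert bonferroni([0.004])[0] == pytest.approx(0.044)
    assert bonferroni([1.0])[0] == 1.0
    # direction: nominal significance lost after correction for 11 tests
    assert bonferroni([0.019])[0] > 0.05


def test_validation_summary_counts():
    counts = [(0, 0), (2, 0), (1, 0), (1, 0), (1, 0), (1, 0), (0, 0),
              (4, 0), (1, 1), (1, 0), (2, 0), (2, 1), (0, 0), (1, 1)]
    assert validation_summary(counts) == (11, 14, 79)
    assert validation_summary([(0, 0)] * 3) == (0, 3, 0)
    assert validation_summary([(1, 0)] * 5) == (5, 5, 100)


def test_embedded_or_recovery():
    """Median estimated risk-class OR across 200 cohorts within 5% of 1.5."""
    region = default_region("test")
    pool = simulate_haplotype_pool(region, n_founders=30, theta_sim=2e-4, seed=90)
    ors = []
    for rep in range(200):
        cohort = sample_cohort(
            pool, n_cases=500, n_controls=500, n_reference=0,
            seed=10_000 + rep, case_class_or={RISK: 1.5},
        )
        case = cohort.chromosome_classes("case") == RISK
        ctrl = cohort.chromosome_classes("control") == RISK
        res = allelic_assoc(int(case.sum()), int((~case).sum()),
                            int(ctrl.sum()), int((~ctrl).sum()))
        ors.append(res.or_hat)
    med = float(np.median(ors))
    assert abs(med - 1.5) / 1.5 < 0.05
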