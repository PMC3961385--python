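"""Case-control allelic association with QC, OR/CI and multiple testing.

The allelic test compares minor-allele counts between affected and
unaffected chromosomes in a 2x2 table: Pearson chi-square (1 df, no
continuity correction) for the p-value, the cross-product odds ratio with
a Wald 95% confidence interval ``exp(ln OR ± 1.96 * SE)``,
``SE = sqrt(1/a + 1/b + 1/c + 1/d)``.  Tables with an empty cell receive
the Haldane–Anscombe +0.5 correction for the OR and CI only (flagged);
the chi-square always uses the raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frequencies import allelic_chisq

__all__ = [
    "AssocResult",
    "allelic_assoc",
    "QcReport",
    "qc_filter",
    "bonferroni",
    "validation_summary",
]


@dataclass
class AssocResult:
    """Allelic 2x2 association result for one variant."""

    a: int  # case minor-allele count
    b: int  # case major-allele count
    c: int  # control minor-allele count
    d: int  # control major-allele count
    or_hat: float
    ci95: tuple[float, float]
    chisq: float
    p: float
    position: int = -1
    haldane: bool = False
    p_bonferroni: float | None = None


def allelic_assoc(a: int, b: int, c: int, d: int, position: int = -1) -> AssocResult:
    """Odds ratio, Wald 95% CI and allelic chi-square for a 2x2 table."""
    if min(a, b, c, d) < 0:
        raise ValueError("allele counts must be non-negative")
    chisq, p = allelic_chisq(a, b, c, d)
    haldane = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if haldane else (a, b, c, d)
    or_hat = (aa * dd) / (bb * cc)
    se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
    log_or = float(np.log(or_hat))
    ci = (float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se)))
    return AssocResult(
        a=a, b=b, c=c, d=d, or_hat=float(or_hat), ci95=ci, chisq=chisq, p=p,
        position=position, haldane=haldane,
    )


@dataclass
class QcReport:
    """Samples and variants removed before association testing."""

    excluded_samples: list[str] = field(default_factory=list)
    excluded_variants: list[int] = field(default_factory=list)
    max_missing: float = 0.10
    min_maf: float = 0.05
    n_samples_kept: int = 0
    n_variants_kept: int = 0


def qc_filter(
    genotypes: np.ndarray,
    sample_ids: list[str],
    positions: np.ndarray,
    max_missing: float = 0.10,
    min_maf: float = 0.05,
) -> tuple[QcReport, np.ndarray, np.ndarray, list[str]]:
    """Pre-association QC on an (S, N) genotype matrix (-1 = missing).

    Samples with per-sample missingness strictly above ``max_missing`` are
    removed first; variants with minor-allele frequency strictly below
    ``min_maf`` — recomputed after the sample removal — are removed second.
    Returns ``(report, filtered matrix, kept positions, kept sample ids)``.
    """
    genotypes = np.asarray(genotypes)
    S, n = genotypes.shape
    if n == 0 or S == 0:
        raise ValueError("empty genotype matrix")
    missing_rate = np.mean(genotypes < 0, axis=0)
    keep_samples = missing_rate <= max_missing
    if not np.any(keep_samples):
        raise ValueError(
            f"QC removed all samples (missingness > {max_missing:.0%} in every sample)"
        )
    sub = genotypes[:, keep_samples]
    mafs = np.empty(S)
    for j in range(S):
        called = sub[j][sub[j] >= 0]
        if called.size == 0:
            mafs[j] = 0.0
            continue
        f = called.sum() / (2 * called.size)
        mafs[j] = min(f, 1 - f)
    keep_variants = mafs >= min_maf
    report = QcReport(
        excluded_samples=[sid for sid, k in zip(sample_ids, keep_samples) if not k],
        excluded_variants=[int(p) for p, k in zip(positions, keep_variants) if not k],
        max_missing=max_missing,
        min_maf=min_maf,
        n_samples_kept=int(keep_samples.sum()),
        n_variants_kept=int(keep_variants.sum()),
    )
    kept_ids = [sid for sid, k in zip(sample_ids, keep_samples) if k]
    return report, sub[keep_variants], np.asarray(positions)[keep_variants], kept_ids


def bonferroni(p_values: list[float] | np.ndarray, n_tests: int = 11) -> np.ndarray:
    """Bonferroni adjustment ``min(1, p * n_tests)``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return np.minimum(1.0, np.asarray(p_values, dtype=float) * n_tests)


def validation_summary(
    allele_counts: list[tuple[int, int]],
) -> tuple[int, int, int]:
    """Novel-variant validation: (n_validated, n_total, percent).

    A variant is validated when its alternate allele is observed at least
    once across affected and unaffected individuals in the orthogonal
    genotyping assay; the percentage is rounded to a whole number.
    """
    n_total = len(allele_counts)
    n_validated = sum(1 for aff, unaff in allele_counts if aff + unaff > 0)
    percent = int(round(100 * n_validated / n_total)) if n_total else 0
    return n_validated, n_total, percent
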