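"""Allele-frequency comparison between a case cohort and a reference panel.

Minor alleles are oriented within the case cohort and the reference
frequency is reported for the same allele, so the signed frequency
difference (freqDIFF) is directly comparable across sites; |freqDIFF| >=
0.05 flags a variant.  The allelic test is a Pearson chi-square on the
2x2 allele-count table without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "minor_allele_freq",
    "FreqRecord",
    "freq_diff",
    "allelic_chisq",
    "novelty_flag",
    "completeness_check",
]

FREQ_DIFF_FLAG = 0.05
P_FLAG = 0.1  # report asterisk threshold


def minor_allele_freq(genotypes: np.ndarray) -> tuple[float, str, dict[str, int], int]:
    """Missing-aware minor-allele frequency of one genotype column.

    ``genotypes`` are alt dosages (-1 = missing).  Returns ``(maf,
    minor_allele, allele_counts, n_called_chromosomes)`` with
    ``minor_allele`` as ``"alt"`` or ``"ref"`` (ties orient to alt) and
    counts keyed the same way.
    """
    g = np.asarray(genotypes)
    called = g[g >= 0]
    if called.size == 0:
        raise ValueError("minor allele frequency undefined: all genotypes missing")
    n_chrom = 2 * called.size
    alt = int(called.sum())
    f_alt = alt / n_chrom
    minor = "alt" if f_alt <= 0.5 else "ref"
    maf = min(f_alt, 1 - f_alt)
    return maf, minor, {"alt": alt, "ref": n_chrom - alt}, n_chrom


@dataclass
class FreqRecord:
    """Case-vs-reference frequency comparison for one variant."""

    position: int
    minor_allele: str  # the case cohort's minor allele ("ref"/"alt")
    maf_case: float
    maf_ref: float
    freq_diff: float
    flagged: bool
    orientation_warning: bool = False  # cohorts disagree on the minor allele
    chisq: float | None = None
    p_value: float | None = None
    novel: bool | None = None


def freq_diff(
    case_alt_freq: float, ref_alt_freq: float, position: int = -1
) -> FreqRecord:
    """Signed case-minus-reference frequency difference, case-minor oriented.

    Both inputs are alternate-allele frequencies; the record reports the
    case cohort's minor allele and the reference frequency of that same
    allele, flagging |difference| >= 0.05 and warning when the reference
    cohort's minor allele differs.
    """
    if not (0 <= case_alt_freq <= 1 and 0 <= ref_alt_freq <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    if case_alt_freq <= 0.5:
        minor, f_case, f_ref = "alt", case_alt_freq, ref_alt_freq
    else:
        minor, f_case, f_ref = "ref", 1 - case_alt_freq, 1 - ref_alt_freq
    diff = f_case - f_ref
    return FreqRecord(
        position=position,
        minor_allele=minor,
        maf_case=f_case,
        maf_ref=f_ref,
        freq_diff=diff,
        flagged=abs(diff) >= FREQ_DIFF_FLAG,
        orientation_warning=f_ref > 0.5,
    )


def allelic_chisq(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Cells are allele counts: (case minor, case major, reference minor,
    reference major).  A zero margin makes the table degenerate:
    (0.0, 1.0) is returned.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("allele counts must be non-negative")
    n = cells.sum()
    if n < 1:
        raise ValueError("empty table")
    margins = (a + b, c + d, a + c, b + d)
    if 0 in margins:
        return 0.0, 1.0
    chisq = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chisq, df=1))
    return float(chisq), p


def novelty_flag(position: int, catalogue: set[int]) -> str:
    """``"known"`` iff the position is in the known-variant catalogue."""
    return "known" if position in catalogue else "novel"


def completeness_check(
    case_variants: set[int],
    ref_variant_freqs: dict[int, float],
    maf_min: float = 0.1,
    excluded: set[int] | None = None,
) -> float | None:
    """Fraction of common reference-panel variants detected in the cases.

    ``ref_variant_freqs`` maps position to the panel minor-allele
    frequency; only panel variants with MAF >= ``maf_min`` enter the
    denominator.  Positions in ``excluded`` (e.g. adjacent to indels and
    hence not comparable between platforms) are honoured and left out.
    Returns None when no common panel variant exists.
    """
    excluded = excluded or set()
    common = {p for p, f in ref_variant_freqs.items() if f >= maf_min} - excluded
    if not common:
        return None
    return len(common & case_variants) / len(common)
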