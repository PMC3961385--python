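"""Haplotype-background analysis.

Chromosomes are classified into RISK / PROT / OTHER backgrounds by strict
matching of their alleles at six tag SNPs.  On top of the classification the
module provides Watterson's nucleotide-diversity estimator stratified by
class, per-variant haplotype-exclusivity codes, the panel-scale segregation
scan, LD (r-squared) tagging, and a windowed EM phaser for unphased
genotype input (an Excoffier–Slatkin-style haplotype-frequency EM with
optional reference-panel augmentation).

Throughout, haplotypes are rows of a ``(n_chromosomes, n_sites)`` matrix of
{0, 1} alleles (-1 = unknown), 0 being the reference allele.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RISK",
    "PROT",
    "OTHER",
    "ND",
    "classify_chromosome",
    "classify_chromosomes",
    "watterson_theta",
    "harmonic_number",
    "DiversityReport",
    "diversity_by_class",
    "exclusivity_code",
    "exclusivity_codes",
    "segregation_scan",
    "ld_r2",
    "tagged_by",
    "phase_em",
]

RISK = "RISK"
PROT = "PROT"
OTHER = "OTHER"
ND = "ND"  # not determined (incomplete phase/genotype at the tag sites)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_chromosome(
    haplotype: np.ndarray,
    tag_idx: np.ndarray,
    risk_alleles: np.ndarray,
    prot_alleles: np.ndarray,
) -> str:
    """Label one phased chromosome by its six tag-SNP alleles.

    RISK/PROT require all six alleles to match the respective pattern;
    anything else (with complete tag genotypes) is OTHER.  A chromosome
    with an unknown allele at any tag site is ND.
    """
    tags = np.asarray(haplotype)[np.asarray(tag_idx)]
    if np.any(tags < 0):
        return ND
    if np.array_equal(tags, np.asarray(risk_alleles)):
        return RISK
    if np.array_equal(tags, np.asarray(prot_alleles)):
        return PROT
    return OTHER


def classify_chromosomes(
    haplotypes: np.ndarray,
    tag_idx: np.ndarray,
    risk_alleles: np.ndarray,
    prot_alleles: np.ndarray,
) -> np.ndarray:
    """Vectorised :func:`classify_chromosome` over matrix rows."""
    return np.array(
        [classify_chromosome(h, tag_idx, risk_alleles, prot_alleles) for h in np.asarray(haplotypes)],
        dtype=object,
    )


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson denominator for n chromosomes."""
    if n < 2:
        raise ValueError("harmonic correction requires n >= 2 chromosomes")
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: int, n: int, L: int) -> float:
    """Per-site Watterson estimator theta = S / (a_n * L).

    S segregating sites observed among n chromosomes over L base pairs;
    unbiased for the population-scaled mutation rate under the
    infinite-sites neutral model.
    """
    if n < 2:
        raise ValueError("theta is undefined for fewer than 2 chromosomes")
    if L < 1:
        raise ValueError("region length must be >= 1")
    if S < 0:
        raise ValueError("segregating-site count must be >= 0")
    return S / (harmonic_number(n) * L)


def _segregating_sites(haps: np.ndarray) -> int:
    """Number of columns with both alleles present (unknowns ignored)."""
    haps = np.asarray(haps)
    known = haps >= 0
    any0 = np.any((haps == 0) & known, axis=0)
    any1 = np.any((haps == 1) & known, axis=0)
    return int(np.sum(any0 & any1))


@dataclass
class DiversityReport:
    """Watterson theta stratified by haplotype class."""

    L: int
    per_class: dict = field(default_factory=dict)  # label -> dict(S, n, a_n, theta)
    overall: dict = field(default_factory=dict)

    def theta(self, label: str) -> float:
        return self.per_class[label]["theta"]

    @property
    def ordering(self) -> list[str]:
        """Class labels sorted by increasing theta."""
        return sorted(self.per_class, key=lambda c: self.per_class[c]["theta"])


def diversity_by_class(
    haplotypes: np.ndarray,
    labels: np.ndarray,
    L: int,
    classes: tuple[str, ...] = (RISK, PROT, OTHER),
) -> DiversityReport:
    """Per-class segregating sites and Watterson theta.

    S_c counts sites polymorphic *within* the class-c chromosomes only, so a
    class of identical chromosomes has theta 0 regardless of cohort-wide
    variation.  Classes with fewer than 2 chromosomes are skipped.
    """
    haplotypes = np.asarray(haplotypes)
    labels = np.asarray(labels, dtype=object)
    report = DiversityReport(L=int(L))
    for label in classes:
        rows = haplotypes[labels == label]
        n = rows.shape[0]
        if n < 2:
            continue
        S = _segregating_sites(rows)
        report.per_class[label] = {
            "S": S,
            "n": n,
            "a_n": harmonic_number(n),
            "theta": watterson_theta(S, n, L),
        }
    n_all = haplotypes.shape[0]
    if n_all >= 2:
        S_all = _segregating_sites(haplotypes)
        report.overall = {
            "S": S_all,
            "n": n_all,
            "a_n": harmonic_number(n_all),
            "theta": watterson_theta(S_all, n_all, L),
        }
    return report


# ---------------------------------------------------------------------------
# exclusivity and segregation
# ---------------------------------------------------------------------------

def _minor_allele(column: np.ndarray) -> int | None:
    """Minor allele (ties -> alternate) of a biallelic column; None if monomorphic."""
    known = column[column >= 0]
    if known.size == 0:
        return None
    f_alt = float(np.mean(known == 1))
    if f_alt == 0.0 or f_alt == 1.0:
        return None
    return 1 if f_alt <= 0.5 else 0


def exclusivity_code(column: np.ndarray, labels: np.ndarray) -> tuple[str, str]:
    """Exclusivity of a variant's minor allele on the risk and protective axes.

    Per axis: ``"2"`` if every carrier chromosome belongs to that class,
    ``"1"`` if carriers include that class and at least one other class,
    ``"0"`` if no chromosome of that class carries the allele, and ``"ND"``
    when any carrier is unphased/unclassified.  Monomorphic variants are
    ``("0", "0")``.
    """
    column = np.asarray(column)
    labels = np.asarray(labels, dtype=object)
    minor = _minor_allele(column)
    if minor is None:
        return ("0", "0")
    carriers = labels[column == minor]
    if carriers.size == 0 or np.any(carriers == ND):
        return (ND, ND) if np.any(carriers == ND) else ("0", "0")

    def axis(cls: str) -> str:
        n_in = int(np.sum(carriers == cls))
        if n_in == 0:
            return "0"
        return "2" if n_in == carriers.size else "1"

    return (axis(RISK), axis(PROT))


def exclusivity_codes(haplotypes: np.ndarray, labels: np.ndarray) -> list[tuple[str, str]]:
    haplotypes = np.asarray(haplotypes)
    return [exclusivity_code(haplotypes[:, j], labels) for j in range(haplotypes.shape[1])]


def segregation_scan(
    haplotypes: np.ndarray, labels: np.ndarray
) -> tuple[list[int], list[int]]:
    """Panel-scale scan for class-segregating variants.

    A variant is *risk-segregating* when its minor allele is carried by at
    least one RISK chromosome and by no PROT chromosome (carriage on OTHER
    chromosomes is irrelevant); protective-segregating is symmetric.
    Unclassified (ND) chromosomes are left out of the scan.  Returns the
    two site-index lists.
    """
    haplotypes = np.asarray(haplotypes)
    labels = np.asarray(labels, dtype=object)
    keep = labels != ND
    haps, labs = haplotypes[keep], labels[keep]
    risk_hits: list[int] = []
    prot_hits: list[int] = []
    for j in range(haps.shape[1]):
        minor = _minor_allele(haps[:, j])
        if minor is None:
            continue
        carriers = labs[haps[:, j] == minor]
        n_risk = int(np.sum(carriers == RISK))
        n_prot = int(np.sum(carriers == PROT))
        if n_risk >= 1 and n_prot == 0:
            risk_hits.append(j)
        if n_prot >= 1 and n_risk == 0:
            prot_hits.append(j)
    return risk_hits, prot_hits


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """r^2 = D^2 / (p_a q_a p_b q_b) on phased haplotypes."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    pa, pb = a.mean(), b.mean()
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom == 0:
        raise ValueError("r^2 undefined for a monomorphic variant")
    D = np.mean(a * b) - pa * pb
    return float(D * D / denom)


def tagged_by(column: np.ndarray, tag_column: np.ndarray, threshold: float = 1.0) -> bool:
    """Whether a variant is tagged by a tag SNP at r^2 >= threshold."""
    return ld_r2(column, tag_column) >= threshold - 1e-12


# ---------------------------------------------------------------------------
# phasing (windowed haplotype-frequency EM)
# ---------------------------------------------------------------------------

def _compatible_pairs(geno: np.ndarray) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered haplotype pairs consistent with one diploid genotype.

    Missing sites are phased as reference (the allele is masked out again
    by the caller).  Heterozygous sites beyond the first each double the
    enumeration, with the first het fixed to break pair symmetry.
    """
    g = np.where(geno < 0, 0, geno)
    het = np.flatnonzero(g == 1)
    base = (g // 2).astype(int)
    if het.size == 0:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    for bits in itertools.product((0, 1), repeat=het.size - 1):
        h1, h2 = base.copy(), base.copy()
        h1[het[0]], h2[het[0]] = 0, 1
        for k, bit in enumerate(bits):
            h1[het[k + 1]], h2[het[k + 1]] = bit, 1 - bit
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def _window_em(
    genotypes: np.ndarray,
    panel: np.ndarray | None,
    n_iter: int,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """EM over haplotype frequencies in one window; returns ML diplotypes.

    Returns ``(haps, ambiguous)`` with ``haps`` of shape (n, 2, w) and a
    per-sample flag set when the best diplotype is not uniquely determined.
    """
    n, w = genotypes.shape
    sample_pairs = [_compatible_pairs(genotypes[i]) for i in range(n)]
    hap_index: dict[tuple[int, ...], int] = {}
    for pairs in sample_pairs:
        for h1, h2 in pairs:
            hap_index.setdefault(h1, len(hap_index))
            hap_index.setdefault(h2, len(hap_index))
    panel_counts = np.zeros(len(hap_index))
    n_panel = 0
    if panel is not None:
        for row in np.asarray(panel):
            h = tuple(int(x) for x in row)
            if h in hap_index:
                panel_counts[hap_index[h]] += 1
                n_panel += 1
    H = len(hap_index)
    freqs = np.full(H, 1.0 / H)
    pair_ids = [
        [(hap_index[h1], hap_index[h2]) for h1, h2 in pairs] for pairs in sample_pairs
    ]
    for _ in range(n_iter):
        counts = panel_counts.copy()
        for ids in pair_ids:
            probs = np.array(
                [(2.0 if i != j else 1.0) * freqs[i] * freqs[j] for i, j in ids]
            )
            total = probs.sum()
            probs = probs / total if total > 0 else np.full(len(ids), 1.0 / len(ids))
            for (i, j), p in zip(ids, probs):
                counts[i] += p
                counts[j] += p
        new = counts / (2 * n + n_panel)
        delta = np.max(np.abs(new - freqs))
        freqs = new
        if delta < tol:
            break
    inv = {v: k for k, v in hap_index.items()}
    haps = np.zeros((n, 2, w), dtype=np.int8)
    ambiguous = np.zeros(n, dtype=bool)
    for s, ids in enumerate(pair_ids):
        probs = np.array([(2.0 if i != j else 1.0) * freqs[i] * freqs[j] for i, j in ids])
        order = np.argsort(-probs)
        best = order[0]
        if len(ids) > 1 and probs[order[0]] - probs[order[1]] < 1e-9:
            ambiguous[s] = True
        i, j = ids[best]
        haps[s, 0], haps[s, 1] = inv[i], inv[j]
    return haps, ambiguous


def phase_em(
    genotypes: np.ndarray,
    window_size: int = 5,
    n_iter: int = 100,
    seed: int = 0,
    panel: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Phase diploid genotypes by windowed haplotype-frequency EM.

    Parameters
    ----------
    genotypes:
        ``(n_samples, n_sites)`` matrix of alt-allele dosages 0/1/2, -1
        missing.
    window_size:
        Sites per EM window (>= 2); windows overlap by half and are
        stitched by majority agreement over the overlap.
    panel:
        Optional ``(n_panel, n_sites)`` known haplotypes counted as
        observed chromosomes in every window's M-step.
    seed:
        Accepted for interface stability; the EM itself is deterministic.

    Returns
    -------
    (haplotypes, uncertain):
        ``haplotypes`` of shape ``(2 * n_samples, n_sites)`` (sample i on
        rows 2i, 2i+1; missing genotypes re-masked to -1) and a per-sample
        boolean ``uncertain`` flag marking ambiguous phase (all-het windows
        with no informative panel, EM ties, or unresolvable stitching).
    """
    genotypes = np.asarray(genotypes)
    n, S = genotypes.shape
    if window_size < 2:
        raise ValueError("window_size must be >= 2 sites")
    window_size = min(window_size, S)
    step = max(1, window_size - max(1, window_size // 2))
    starts = list(range(0, max(S - window_size, 0) + 1, step))
    if starts[-1] + window_size < S:
        starts.append(S - window_size)

    out = np.full((n, 2, S), -9, dtype=np.int8)
    uncertain = np.zeros(n, dtype=bool)
    for w_i, start in enumerate(starts):
        stop = start + window_size
        win_panel = panel[:, start:stop] if panel is not None else None
        haps, amb = _window_em(genotypes[:, start:stop], win_panel, n_iter)
        uncertain |= amb
        for s in range(n):
            if w_i == 0:
                out[s, :, start:stop] = haps[s]
                continue
            overlap = np.arange(start, min(stop, starts[w_i - 1] + window_size))
            rel = overlap - start
            agree = np.sum(out[s, 0, overlap] == haps[s, 0, rel]) + np.sum(
                out[s, 1, overlap] == haps[s, 1, rel]
            )
            swapped = np.sum(out[s, 0, overlap] == haps[s, 1, rel]) + np.sum(
                out[s, 1, overlap] == haps[s, 0, rel]
            )
            if agree == swapped and np.any(genotypes[s, overlap] == 1):
                uncertain[s] = True
            pair = haps[s] if agree >= swapped else haps[s, ::-1]
            out[s, :, start:stop] = pair
    phased = out.reshape(n * 2, S).astype(np.int8)
    missing = np.repeat(genotypes < 0, 2, axis=0)
    phased[missing] = -1
    return phased, uncertain
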