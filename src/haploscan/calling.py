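"""Probabilistic diploid genotype calling from pileup allele counts.

The model is the standard symmetric-error biallelic likelihood: a read
matches a homozygous genotype's allele with probability ``1 - eps`` and
mismatches to a specific base with ``eps / 3``; under a heterozygote a read
reports either allele with probability ``0.5 * (1 - eps) + 0.5 * (eps / 3)``.
"Other"-base reads are equally likely under all three genotypes and cancel
out of the likelihood ratios.  Cohort alternate-allele frequency is
estimated per site by an EM over the diploid Hardy-Weinberg mixture of the
per-sample likelihood triples; calls are maximum-posterior under the
HWE prior at the estimated frequency.  GQ is the phred-scaled likelihood
ratio of the best to second-best genotype (second-smallest PL, capped at
99).

A deliberately naive per-sample threshold caller (fixed minimum read count
and allele fraction) provides the second, independent call set, and
``classify_caller_sets`` assigns each variant the consensus code used in
dual-caller comparisons: 1 = both callers, 2 = probabilistic caller only,
3a = naive caller only, 3b = naive caller only but present among the
probabilistic caller's filtered sites, 4 = supplementary (Sanger-region)
calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeLikelihood",
    "genotype_likelihoods",
    "estimate_cohort_af",
    "SiteCallStats",
    "call_site",
    "CallSet",
    "call_pileups",
    "hard_filter",
    "DEFAULT_FILTER_THRESHOLDS",
    "naive_caller",
    "naive_call_matrix",
    "classify_caller_sets",
]

GQ_CAP = 99

# thresholds in the QD<5.0 regime (stricter than the generic QD<2.0
# recommendation, which lets low-QD/high-AF artefact calls through);
# MQ / HaplotypeScore keys are accepted but inert: no alignment layer exists.
DEFAULT_FILTER_THRESHOLDS = {"QD": 5.0, "FS": 60.0, "RPRS": -8.0}
_INERT_THRESHOLDS = {"MQ", "HaplotypeScore", "MQRankSum"}


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _log10_lik(ref_count: np.ndarray, alt_count: np.ndarray, epsilon: float) -> np.ndarray:
    """log10 likelihood triples (RR, RA, AA), shape (..., 3)."""
    ref_count = np.asarray(ref_count, dtype=float)
    alt_count = np.asarray(alt_count, dtype=float)
    match, mismatch = np.log10(1 - epsilon), np.log10(epsilon / 3.0)
    het = np.log10(0.5 * (1 - epsilon) + 0.5 * epsilon / 3.0)
    return np.stack(
        [
            ref_count * match + alt_count * mismatch,
            (ref_count + alt_count) * het,
            ref_count * mismatch + alt_count * match,
        ],
        axis=-1,
    )


def _pl_from_log10(l10: np.ndarray) -> np.ndarray:
    pl = np.rint(-10.0 * (l10 - l10.max(axis=-1, keepdims=True))).astype(np.int64)
    return pl


def _gq_from_pl(pl: np.ndarray) -> np.ndarray:
    return np.minimum(np.sort(pl, axis=-1)[..., 1], GQ_CAP)


@dataclass
class GenotypeLikelihood:
    """Per-sample likelihood triple with its phred summary.

    ``pl`` is normalised so the best genotype has PL 0; ``gq`` is the
    second-smallest PL capped at 99 — the phred gap between the two best
    genotypes.  ``posterior`` is filled in once a cohort allele frequency
    is available.
    """

    log10_lik: tuple[float, float, float]
    pl: tuple[int, int, int]
    gq: int
    missing: bool = False
    posterior: tuple[float, float, float] | None = None


def genotype_likelihoods(ref_count: int, alt_count: int, epsilon: float) -> GenotypeLikelihood:
    """Likelihood triple for one sample at one site.

    Zero total depth yields flat likelihoods, a missing call and GQ 0.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    if ref_count + alt_count == 0:
        return GenotypeLikelihood(log10_lik=(0.0, 0.0, 0.0), pl=(0, 0, 0), gq=0, missing=True)
    l10 = _log10_lik(ref_count, alt_count, epsilon)
    pl = _pl_from_log10(l10)
    return GenotypeLikelihood(
        log10_lik=tuple(float(x) for x in l10),
        pl=tuple(int(x) for x in pl),
        gq=int(_gq_from_pl(pl)),
    )


# ---------------------------------------------------------------------------
# cohort allele frequency (EM)
# ---------------------------------------------------------------------------

def _hwe_prior(af: np.ndarray) -> np.ndarray:
    af = np.asarray(af, dtype=float)
    return np.stack([(1 - af) ** 2, 2 * af * (1 - af), af**2], axis=-1)


def _af_em_matrix(
    l10: np.ndarray, has_data: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """Vectorised per-site EM; l10 (S, N, 3), has_data (S, N) -> af (S,)."""
    lik = np.power(10.0, l10 - l10.max(axis=-1, keepdims=True))
    lik = np.where(has_data[..., None], lik, 1.0)
    n_called = has_data.sum(axis=1)
    af = np.full(l10.shape[0], 0.05)
    dosage = np.array([0.0, 1.0, 2.0])
    for _ in range(max_iter):
        prior = _hwe_prior(af)[:, None, :]
        w = lik * prior
        w_sum = w.sum(axis=-1, keepdims=True)
        w = np.divide(w, w_sum, out=np.full_like(w, 1.0 / 3.0), where=w_sum > 0)
        e_alt = (w @ dosage) * has_data
        with np.errstate(invalid="ignore", divide="ignore"):
            new = e_alt.sum(axis=1) / (2.0 * n_called)
        new = np.where(n_called > 0, new, np.nan)
        delta = np.nanmax(np.abs(new - af)) if np.any(n_called > 0) else 0.0
        af = new
        if delta < tol:
            break
    return af


def estimate_cohort_af(gl_matrix: np.ndarray, has_data: np.ndarray | None = None) -> float:
    """EM estimate of the alternate-allele frequency at one site.

    ``gl_matrix`` holds per-sample log10 likelihood triples (N, 3);
    samples without data may be masked with ``has_data``.  Raises when no
    sample carries data (the site is dropped upstream).
    """
    gl_matrix = np.asarray(gl_matrix, dtype=float)
    if has_data is None:
        has_data = np.ones(gl_matrix.shape[0], dtype=bool)
    if not np.any(has_data):
        raise ValueError("allele frequency undefined: all samples missing")
    af = _af_em_matrix(gl_matrix[None, ...], np.asarray(has_data)[None, ...])
    return float(af[0])


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------

@dataclass
class SiteCallStats:
    """Site-level statistics accompanying a called variant."""

    pos: int
    alt_af_hat: float
    qual: float
    qd: float
    fs_phred: float
    rp_ranksum: float
    depth_carriers: int = 0
    tie_broken: bool = False


def _posterior(l10: np.ndarray, af: float) -> np.ndarray:
    lik = np.power(10.0, l10 - l10.max(axis=-1, keepdims=True))
    w = lik * _hwe_prior(np.array(af))
    return w / w.sum(axis=-1, keepdims=True)


def call_site(
    gl_matrix: np.ndarray,
    af_hat: float,
    depths: np.ndarray | None = None,
    has_data: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, SiteCallStats]:
    """Maximum-posterior genotype per sample plus site statistics.

    Returns ``(calls, posterior, stats)`` where calls are alt dosages with
    -1 for missing samples.  Posterior ties resolve toward fewer alternate
    alleles (argmax over the RR, RA, AA ordering).  Site QUAL is the phred
    probability that no sample carries an alternate allele; QD divides it
    by the total depth of samples called non-reference.
    """
    gl_matrix = np.asarray(gl_matrix, dtype=float)
    n = gl_matrix.shape[0]
    if has_data is None:
        has_data = np.ones(n, dtype=bool)
    post = _posterior(gl_matrix, af_hat)
    calls = np.argmax(post, axis=-1).astype(np.int8)
    sorted_post = np.sort(post, axis=-1)
    ties = (sorted_post[:, -1] - sorted_post[:, -2]) < 1e-12
    calls[~has_data] = -1
    with np.errstate(divide="ignore"):
        qual = float(np.sum(-10.0 * np.log10(np.clip(post[has_data, 0], 1e-300, None))))
    carriers = (calls > 0) & has_data
    depth_carriers = int(depths[carriers].sum()) if depths is not None else 0
    qd = qual / depth_carriers if depth_carriers > 0 else 0.0
    stats_ = SiteCallStats(
        pos=-1,
        alt_af_hat=float(af_hat),
        qual=qual,
        qd=qd,
        fs_phred=0.0,
        rp_ranksum=0.0,
        depth_carriers=depth_carriers,
        tie_broken=bool(np.any(ties & has_data)),
    )
    return calls, post, stats_


def _allele_balance_stats(
    ref_counts: np.ndarray, alt_counts: np.ndarray, het_mask: np.ndarray
) -> tuple[float, float]:
    """FS analog (phred allele-balance exact test) and rank-sum z."""
    r = ref_counts[het_mask]
    a = alt_counts[het_mask]
    if a.size == 0:
        return 0.0, 0.0
    n_alt, n_tot = int(a.sum()), int(a.sum() + r.sum())
    if n_tot == 0:
        return 0.0, 0.0
    p = stats.binomtest(n_alt, n_tot, 0.5).pvalue
    fs = float(-10.0 * np.log10(max(p, 1e-300)))
    rprs = 0.0
    if a.size >= 2:
        rprs = float(stats.ranksums(a, r).statistic)
    return fs, rprs


# ---------------------------------------------------------------------------
# cohort-scale calling
# ---------------------------------------------------------------------------

@dataclass
class CallSet:
    """Genotype calls over candidate sites for a cohort of samples."""

    positions: np.ndarray
    sample_ids: list[str]
    genotypes: np.ndarray  # (S, N) alt dosage, -1 missing
    gq: np.ndarray  # (S, N)
    pl: np.ndarray  # (S, N, 3)
    af: np.ndarray  # (S,)
    qual: np.ndarray
    stats: list[SiteCallStats] = field(default_factory=list)
    variant_mask: np.ndarray | None = None  # sites with >= 1 non-ref call
    filter_status: dict[int, tuple[bool, tuple[str, ...]]] = field(default_factory=dict)

    @property
    def variant_positions(self) -> np.ndarray:
        return self.positions[self.variant_mask]

    def passed_positions(self) -> set[int]:
        return {p for p, (ok, _) in self.filter_status.items() if ok}

    def failed_positions(self) -> set[int]:
        return {p for p, (ok, _) in self.filter_status.items() if not ok}


def call_pileups(
    pileup_frame: pd.DataFrame,
    epsilon: float = 0.01,
    thresholds: dict[str, float] | None = None,
) -> CallSet:
    """Run the probabilistic caller over a pileup table.

    Sites are the distinct positions in the table; samples without a row
    at a site are treated as missing there.  Variant sites (any non-ref
    call) are hard-filtered with :func:`hard_filter` and their status kept
    either way — filtered sites remain visible for dual-caller set codes.
    """
    from .simulate import PileupSet  # local import to avoid a cycle

    positions, samples, ref, alt, other = PileupSet(pileup_frame).site_matrix()
    S, n = ref.shape
    depth = ref + alt + other
    has_data = depth > 0
    l10 = _log10_lik(ref, alt, epsilon)
    af = _af_em_matrix(l10, has_data)
    af_filled = np.where(np.isnan(af), 0.0, af)

    lik = np.power(10.0, l10 - l10.max(axis=-1, keepdims=True))
    prior = _hwe_prior(af_filled)[:, None, :]
    w = lik * prior
    post = w / w.sum(axis=-1, keepdims=True)

    calls = np.argmax(post, axis=-1).astype(np.int8)
    calls[~has_data] = -1
    pl = _pl_from_log10(l10)
    pl[~has_data] = 0
    gq = _gq_from_pl(pl)
    gq[~has_data] = 0

    with np.errstate(divide="ignore"):
        log_rr = -10.0 * np.log10(np.clip(post[..., 0], 1e-300, None))
    qual = np.where(has_data, log_rr, 0.0).sum(axis=1)

    variant_mask = np.any(calls > 0, axis=1)
    stats_list: list[SiteCallStats] = []
    filter_status: dict[int, tuple[bool, tuple[str, ...]]] = {}
    for j in np.flatnonzero(variant_mask):
        carriers = calls[j] > 0
        depth_car = int(depth[j][carriers].sum())
        qd = qual[j] / depth_car if depth_car > 0 else 0.0
        fs, rprs = _allele_balance_stats(ref[j], alt[j], calls[j] == 1)
        st = SiteCallStats(
            pos=int(positions[j]),
            alt_af_hat=float(af_filled[j]),
            qual=float(qual[j]),
            qd=qd,
            fs_phred=fs,
            rp_ranksum=rprs,
            depth_carriers=depth_car,
        )
        stats_list.append(st)
        filter_status[int(positions[j])] = hard_filter(st, thresholds)

    return CallSet(
        positions=positions,
        sample_ids=samples,
        genotypes=calls,
        gq=gq,
        pl=pl,
        af=af_filled,
        qual=qual,
        stats=stats_list,
        variant_mask=variant_mask,
        filter_status=filter_status,
    )


# ---------------------------------------------------------------------------
# hard filtering
# ---------------------------------------------------------------------------

def hard_filter(
    stats_: SiteCallStats, thresholds: dict[str, float] | None = None
) -> tuple[bool, tuple[str, ...]]:
    """Apply hard site filters; returns (passed, failure reasons).

    Boundary convention: strictly-less-than fails QD (QD == threshold
    passes), strictly-greater fails FS, strictly-less fails RPRS.  Unknown
    alignment-level thresholds (MQ, HaplotypeScore, MQRankSum) are accepted
    in the mapping but have no effect.
    """
    th = dict(DEFAULT_FILTER_THRESHOLDS)
    if thresholds:
        for key, val in thresholds.items():
            if key in _INERT_THRESHOLDS:
                continue
            th[key] = val
    reasons = []
    if stats_.qd < th["QD"]:
        reasons.append("LowQD")
    if stats_.fs_phred > th["FS"]:
        reasons.append("HighFS")
    if stats_.rp_ranksum < th["RPRS"]:
        reasons.append("LowRPRS")
    return (len(reasons) == 0, tuple(reasons))


# ---------------------------------------------------------------------------
# naive threshold caller
# ---------------------------------------------------------------------------

def naive_caller(
    ref_count: int,
    alt_count: int,
    min_reads: int = 3,
    min_fraction: float = 0.2,
    hom_fraction: float = 0.8,
) -> int:
    """Per-sample threshold genotype: -1 missing, 0 hom-ref, 1 het, 2 hom-alt.

    Non-reference is called iff ``alt_count >= min_reads`` and the alt
    fraction is at least ``min_fraction``; hom-alt requires
    ``hom_fraction``.
    """
    depth = ref_count + alt_count
    if depth == 0:
        return -1
    frac = alt_count / depth
    if alt_count >= min_reads and frac >= min_fraction:
        return 2 if frac >= hom_fraction else 1
    return 0


def naive_call_matrix(
    pileup_frame: pd.DataFrame,
    min_reads: int = 3,
    min_fraction: float = 0.2,
    hom_fraction: float = 0.8,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Vectorised naive caller; returns (positions, sample_ids, genotypes)."""
    from .simulate import PileupSet

    positions, samples, ref, alt, _ = PileupSet(pileup_frame).site_matrix()
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    nonref = (alt >= min_reads) & (frac >= min_fraction)
    geno = np.where(nonref, np.where(frac >= hom_fraction, 2, 1), 0).astype(np.int8)
    geno[depth == 0] = -1
    return positions, samples, geno


# ---------------------------------------------------------------------------
# dual-caller set classification
# ---------------------------------------------------------------------------

def classify_caller_sets(
    calls_naive: set[int],
    calls_prob_pass: set[int],
    calls_prob_fail: set[int],
    calls_supplementary: set[int] | None = None,
) -> tuple[dict[int, str], dict[str, int]]:
    """Assign each variant position a dual-caller consensus code.

    Codes: ``1`` both callers (naive and probabilistic-passed), ``2``
    probabilistic only, ``3a`` naive only (absent from the probabilistic
    caller entirely), ``3b`` naive only but present among the
    probabilistic caller's filtered calls, ``4`` supplementary-region
    only.  The summary reports the set sizes with the inclusion–exclusion
    union |A| + |B| - |A ∩ B|.
    """
    calls_supplementary = calls_supplementary or set()
    overlap = calls_prob_pass & calls_prob_fail
    if overlap:
        raise ValueError(f"variants in both passed and failed sets: {sorted(overlap)[:5]}")
    codes: dict[int, str] = {}
    for p in calls_naive | calls_prob_pass | calls_supplementary:
        if p in calls_naive and p in calls_prob_pass:
            codes[p] = "1"
        elif p in calls_prob_pass:
            codes[p] = "2"
        elif p in calls_naive:
            codes[p] = "3b" if p in calls_prob_fail else "3a"
        else:
            codes[p] = "4"
    inter = len(calls_naive & calls_prob_pass)
    summary = {
        "n_naive": len(calls_naive),
        "n_prob_pass": len(calls_prob_pass),
        "n_intersection": inter,
        "n_union": len(calls_naive) + len(calls_prob_pass) - inter,
        "n_supplementary_only": sum(1 for c in codes.values() if c == "4"),
    }
    return codes, summary
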