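"""Synthetic study generator.

Builds a fully specified synthetic amplicon-resequencing study with the
statistical structure the downstream analysis assumes: a founder haplotype
pool carrying designated 6-SNP risk/protective backgrounds on top of
neutral infinite-sites variation, a diploid cohort (cases, optional
controls, and a reference panel standing in for a population sample),
per-site per-sample pileup allele counts with amplicon-structured depth and
homopolymer-elevated base error, an array-genotyped truth subset, a
known-variant catalogue, and regulatory annotation tracks with controlled
overlap.

The founder genealogy is a standard single-population Kingman coalescent
(simulated with msprime) with mutations dropped under an infinite-sites
scheme, so the expected number of segregating sites among n founders is
``theta * L * a_n`` — exactly the quantity the Watterson estimator inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .haplotypes import OTHER, PROT, RISK, classify_chromosomes
from .region import RegionModel

__all__ = [
    "TagSpec",
    "HaplotypePool",
    "Cohort",
    "DepthModel",
    "ErrorModel",
    "default_tag_spec",
    "simulate_haplotype_pool",
    "simulate_stratified_pool",
    "sample_cohort",
    "PileupSet",
    "simulate_pileups",
]

CASE = "case"
CONTROL = "control"
REFERENCE = "reference"

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class TagSpec:
    """The six tag SNPs defining the risk and protective backgrounds."""

    positions: tuple[int, ...]
    risk_alleles: tuple[int, ...]
    prot_alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != 6:
            raise ValueError("exactly six tag positions are required")
        if len(set(self.positions)) != 6:
            raise ValueError("tag positions collide")
        if tuple(self.risk_alleles) == tuple(self.prot_alleles):
            raise ValueError("risk and protective tag patterns must differ")


def default_tag_spec(region: RegionModel) -> TagSpec:
    """Six tag sites spread over the region, risk = all-alt, protective = all-ref."""
    L = region.length_bp
    positions = tuple(int(round(f * L)) for f in (0.21, 0.33, 0.45, 0.58, 0.71, 0.84))
    return TagSpec(positions=positions, risk_alleles=(1, 1, 1, 1, 1, 1), prot_alleles=(0, 0, 0, 0, 0, 0))


@dataclass
class HaplotypePool:
    """Founder haplotypes over polymorphic sites in ``[0, L)``.

    ``haplotypes`` is (n_founders, n_sites) of {0, 1}; ``positions`` are
    0-based and strictly increasing; ``tag_idx`` indexes the six tag sites.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    ref_bases: np.ndarray
    alt_bases: np.ndarray
    tag_idx: np.ndarray
    risk_alleles: np.ndarray
    prot_alleles: np.ndarray
    founder_frequencies: np.ndarray
    founder_class: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.founder_class is None:
            self.founder_class = classify_chromosomes(
                self.haplotypes, self.tag_idx, self.risk_alleles, self.prot_alleles
            )
        if not np.isclose(self.founder_frequencies.sum(), 1.0):
            raise ValueError("founder frequencies must sum to 1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("site positions must be strictly increasing")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequencies(self, weights: np.ndarray | None = None) -> np.ndarray:
        """Population alt-allele frequency per site under founder weights."""
        w = self.founder_frequencies if weights is None else weights
        return w @ self.haplotypes

    def class_frequencies(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for label in (RISK, PROT, OTHER):
            out[label] = float(self.founder_frequencies[self.founder_class == label].sum())
        return out


def _coalescent_sites(
    L: int,
    n_founders: int,
    theta: float,
    rng: np.random.Generator,
    forbidden: set[int],
    n_blocks: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Infinite-sites variation on Kingman genealogies over the founders.

    Returns ``(positions, genotypes)`` with genotypes (n_founders, S).
    Time units are chosen so the pairwise coalescence rate is 1, hence a
    per-unit-length mutation rate of theta/2 yields E[S] = theta * L * a_n
    exactly.  With ``n_blocks > 1`` the region is split into that many
    stretches with independent genealogies (a crude stand-in for
    recombination along the region); the expectation is unchanged while
    the single-tree variance component shrinks by 1/n_blocks.
    """
    if theta == 0:
        return np.empty(0, dtype=np.int64), np.empty((n_founders, 0), dtype=np.int8)
    bounds = np.linspace(0, L, n_blocks + 1).astype(np.int64)
    all_pos: list[int] = []
    all_geno: list[np.ndarray] = []
    used = set(forbidden)
    for b in range(n_blocks):
        offset, block_len = int(bounds[b]), int(bounds[b + 1] - bounds[b])
        if block_len == 0:
            continue
        seed_anc, seed_mut = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples=n_founders,
            ploidy=1,
            population_size=1,
            sequence_length=block_len,
            random_seed=int(seed_anc),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=theta / 2.0,
            random_seed=int(seed_mut),
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
        )
        raw_pos = [site.position for site in mts.sites()]
        geno = mts.genotype_matrix().T.astype(np.int8)  # founders x sites
        for j, p in enumerate(raw_pos):
            q = offset + int(np.floor(p))
            while q in used and q < L - 1:
                q += 1
            if q in used or q >= L:
                continue  # overcrowded neighbourhood; drop (vanishingly rare)
            used.add(q)
            all_pos.append(q)
            all_geno.append(geno[:, j])
    positions = np.asarray(all_pos, dtype=np.int64)
    geno = (
        np.stack(all_geno, axis=1)
        if all_geno
        else np.empty((n_founders, 0), dtype=np.int8)
    )
    order = np.argsort(positions)
    return positions[order], geno[:, order]


def _founder_class_counts(n_founders: int, class_fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    if n_founders < 4:
        raise ValueError("need at least 4 founders")
    n_risk = max(1, int(round(class_fractions[0] * n_founders)))
    n_prot = max(1, int(round(class_fractions[1] * n_founders)))
    n_other = n_founders - n_risk - n_prot
    if n_other < 1:
        raise ValueError("class fractions leave no OTHER founders")
    return n_risk, n_prot, n_other


def _other_tag_patterns(
    n: int, tag_spec: TagSpec, rng: np.random.Generator
) -> np.ndarray:
    """Tag patterns for OTHER founders, distinct from both named patterns."""
    risk = np.asarray(tag_spec.risk_alleles)
    prot = np.asarray(tag_spec.prot_alleles)
    out = np.empty((n, 6), dtype=np.int8)
    for i in range(n):
        while True:
            pat = rng.integers(0, 2, size=6).astype(np.int8)
            if not np.array_equal(pat, risk) and not np.array_equal(pat, prot):
                out[i] = pat
                break
    return out


def _assemble_pool(
    region: RegionModel,
    tag_spec: TagSpec,
    bg_positions: np.ndarray,
    bg_geno: np.ndarray,
    tag_matrix: np.ndarray,
    founder_frequencies: np.ndarray,
    rng: np.random.Generator,
) -> HaplotypePool:
    tag_pos = np.asarray(tag_spec.positions, dtype=np.int64)
    positions = np.concatenate([bg_positions, tag_pos])
    haps = np.concatenate([bg_geno, tag_matrix], axis=1)
    order = np.argsort(positions)
    positions, haps = positions[order], haps[:, order]
    tag_idx = np.searchsorted(positions, tag_pos)
    ref = _BASES[rng.integers(0, 4, size=positions.size)]
    alt = np.array([_BASES[(np.flatnonzero(_BASES != r)[rng.integers(0, 3)])] for r in ref])
    return HaplotypePool(
        haplotypes=haps.astype(np.int8),
        positions=positions,
        ref_bases=ref,
        alt_bases=alt,
        tag_idx=tag_idx,
        risk_alleles=np.asarray(tag_spec.risk_alleles, dtype=np.int8),
        prot_alleles=np.asarray(tag_spec.prot_alleles, dtype=np.int8),
        founder_frequencies=founder_frequencies,
    )


def simulate_haplotype_pool(
    region: RegionModel,
    n_founders: int,
    theta_sim: float,
    tag_spec: TagSpec | None = None,
    seed: int = 0,
    class_fractions: tuple[float, float, float] = (0.365, 0.121, 0.514),
    within_class_dirichlet: float | None = 1.0,
    n_blocks: int = 1,
) -> HaplotypePool:
    """Founder pool: shared neutral background plus 6-SNP class structure.

    Founders are partitioned into RISK/PROT/OTHER groups according to
    ``class_fractions`` (defaults mirror a European reference panel where
    127 and 42 of 348 chromosomes carry the risk and protective
    backgrounds); the tag sites are overwritten with the class patterns and
    all other variation comes from a single infinite-sites coalescent at
    per-site rate ``theta_sim``.  Founder frequencies are a Dirichlet split
    within each class (uniform when ``within_class_dirichlet`` is None),
    scaled to the class fractions.
    """
    if tag_spec is None:
        tag_spec = default_tag_spec(region)
    rng = np.random.default_rng(seed)
    n_risk, n_prot, n_other = _founder_class_counts(n_founders, class_fractions)
    bg_pos, bg_geno = _coalescent_sites(
        region.length_bp, n_founders, theta_sim, rng, set(tag_spec.positions),
        n_blocks=n_blocks,
    )
    tag_matrix = np.concatenate(
        [
            np.tile(np.asarray(tag_spec.risk_alleles, dtype=np.int8), (n_risk, 1)),
            np.tile(np.asarray(tag_spec.prot_alleles, dtype=np.int8), (n_prot, 1)),
            _other_tag_patterns(n_other, tag_spec, rng),
        ]
    )
    freqs = np.empty(n_founders)
    start = 0
    for count, frac in zip((n_risk, n_prot, n_other), class_fractions):
        if within_class_dirichlet is None:
            split = np.full(count, 1.0 / count)
        else:
            split = rng.dirichlet(np.full(count, within_class_dirichlet))
        freqs[start : start + count] = frac * split
        start += count
    freqs /= freqs.sum()
    return _assemble_pool(region, tag_spec, bg_pos, bg_geno, tag_matrix, freqs, rng)


def simulate_stratified_pool(
    region: RegionModel,
    founders_per_class: tuple[int, int, int],
    theta_per_class: tuple[float, float, float],
    tag_spec: TagSpec | None = None,
    seed: int = 0,
    class_fractions: tuple[float, float, float] = (0.42, 0.14, 0.44),
    n_blocks: int = 10,
) -> HaplotypePool:
    """Pool with an independent within-class mutation rate per background.

    Each class's founders get background variation from their own
    coalescent at the class's theta (sites are disjoint across classes
    under infinite sites), so the within-class nucleotide diversity is
    controlled directly — the construction behind class-stratified
    diversity recovery experiments.
    """
    if tag_spec is None:
        tag_spec = default_tag_spec(region)
    rng = np.random.default_rng(seed)
    n_risk, n_prot, n_other = founders_per_class
    n_founders = n_risk + n_prot + n_other
    forbidden = set(tag_spec.positions)
    blocks = []  # (positions, per-class genotypes)
    for count, theta in zip(founders_per_class, theta_per_class):
        pos, geno = _coalescent_sites(
            region.length_bp, count, theta, rng, forbidden, n_blocks=n_blocks
        )
        forbidden |= set(int(p) for p in pos)
        blocks.append((pos, geno))
    all_pos = np.concatenate([b[0] for b in blocks])
    bg = np.zeros((n_founders, all_pos.size), dtype=np.int8)
    col = 0
    row = 0
    for count, (pos, geno) in zip(founders_per_class, blocks):
        bg[row : row + count, col : col + pos.size] = geno
        col += pos.size
        row += count
    order = np.argsort(all_pos)
    tag_matrix = np.concatenate(
        [
            np.tile(np.asarray(tag_spec.risk_alleles, dtype=np.int8), (n_risk, 1)),
            np.tile(np.asarray(tag_spec.prot_alleles, dtype=np.int8), (n_prot, 1)),
            _other_tag_patterns(n_other, tag_spec, rng),
        ]
    )
    freqs = np.concatenate(
        [np.full(c, f / c) for c, f in zip(founders_per_class, class_fractions)]
    )
    freqs /= freqs.sum()
    return _assemble_pool(
        region, tag_spec, all_pos[order], bg[:, order], tag_matrix, freqs, rng
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Diploid individuals drawn from the founder pool.

    ``chrom_founders`` is (n_individuals, 2) founder indices; the truth
    diplotype of individual i is the corresponding pair of founder
    haplotypes.  ``array_truth_idx`` indexes the sites assumed to be
    genotyped perfectly on an orthogonal array platform.
    """

    pool: HaplotypePool
    sample_ids: list[str]
    statuses: np.ndarray
    chrom_founders: np.ndarray
    array_truth_idx: np.ndarray

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    def indices(self, status: str) -> np.ndarray:
        return np.flatnonzero(self.statuses == status)

    def haplotype_matrix(self, status: str | None = None) -> np.ndarray:
        """(2k, n_sites) truth chromosome matrix for a status subset."""
        idx = np.arange(self.n_individuals) if status is None else self.indices(status)
        founders = self.chrom_founders[idx].reshape(-1)
        return self.pool.haplotypes[founders]

    def chromosome_classes(self, status: str | None = None) -> np.ndarray:
        idx = np.arange(self.n_individuals) if status is None else self.indices(status)
        founders = self.chrom_founders[idx].reshape(-1)
        return self.pool.founder_class[founders]

    def genotype_matrix(self, status: str | None = None) -> np.ndarray:
        """(n_sites, k) alt-dosage truth genotypes for a status subset."""
        idx = np.arange(self.n_individuals) if status is None else self.indices(status)
        h = self.pool.haplotypes
        return (h[self.chrom_founders[idx, 0]] + h[self.chrom_founders[idx, 1]]).T

    def ids(self, status: str | None = None) -> list[str]:
        if status is None:
            return list(self.sample_ids)
        return [self.sample_ids[i] for i in self.indices(status)]


def _shift_class_frequencies(
    pool: HaplotypePool, class_or: dict[str, float]
) -> np.ndarray:
    """Founder frequencies after shifting class odds by the given ORs."""
    freqs = pool.founder_frequencies.copy()
    for label, odds_ratio in class_or.items():
        mask = pool.founder_class == label
        p = freqs[mask].sum()
        if p <= 0 or p >= 1 or odds_ratio == 1.0:
            continue
        odds = odds_ratio * p / (1 - p)
        p_new = odds / (1 + odds)
        freqs[mask] *= p_new / p
        freqs[~mask] *= (1 - p_new) / (1 - p)
    return freqs / freqs.sum()


def sample_cohort(
    pool: HaplotypePool,
    n_cases: int,
    n_controls: int,
    n_reference: int,
    seed: int = 0,
    case_class_or: dict[str, float] | None = None,
    array_truth_fraction: float = 0.5,
    array_maf_min: float = 0.05,
) -> Cohort:
    """Draw a diploid cohort chromosome-by-chromosome from the pool.

    Each chromosome is an independent draw from the founder frequencies;
    cases optionally use class-odds-shifted frequencies (``case_class_or``,
    default ``{"RISK": 1.3}``) so association analysis has a recoverable
    effect.  The array-truth subset is a random ``array_truth_fraction`` of
    sites common in the pool (population frequency within
    ``[array_maf_min, 1 - array_maf_min]``), always including the tags.
    """
    if pool.n_founders == 0:
        raise ValueError("empty founder pool")
    if case_class_or is None:
        case_class_or = {RISK: 1.3}
    rng = np.random.default_rng(seed)
    case_freqs = _shift_class_frequencies(pool, case_class_or)
    base = pool.founder_frequencies

    ids: list[str] = []
    statuses: list[str] = []
    draws: list[np.ndarray] = []
    for status, count, freqs, prefix in (
        (CASE, n_cases, case_freqs, "case"),
        (CONTROL, n_controls, base, "ctrl"),
        (REFERENCE, n_reference, base, "ref"),
    ):
        if count:
            draws.append(rng.choice(pool.n_founders, size=(count, 2), p=freqs))
            ids.extend(f"{prefix}{i + 1:03d}" for i in range(count))
            statuses.extend([status] * count)
    chrom_founders = (
        np.concatenate(draws) if draws else np.empty((0, 2), dtype=np.int64)
    )

    pop_af = pool.allele_frequencies()
    common = np.flatnonzero((pop_af >= array_maf_min) & (pop_af <= 1 - array_maf_min))
    n_pick = int(round(array_truth_fraction * common.size))
    picked = rng.choice(common, size=min(n_pick, common.size), replace=False) if common.size else np.empty(0, int)
    array_idx = np.union1d(picked, pool.tag_idx)

    return Cohort(
        pool=pool,
        sample_ids=ids,
        statuses=np.array(statuses, dtype=object),
        chrom_founders=chrom_founders,
        array_truth_idx=array_idx.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# depth / error models and pileups
# ---------------------------------------------------------------------------

@dataclass
class DepthModel:
    """Amplicon-structured sequencing depth.

    Site depth is Poisson with mean ``amplicon mean x lognormal
    sample-amplicon factor x lognormal site factor``; the lognormal factors
    are mean-one, reproducing the blocky per-amplicon x per-sample
    structure of pooled amplicon libraries.  Sites in declared gaps get
    depth 0.
    """

    per_amplicon_mean: tuple[float, ...] = (25.0, 32.0, 18.0, 22.0, 35.0, 30.0, 12.0, 24.0)
    sample_scale_dispersion: float = 0.5
    site_dispersion: float = 0.3

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.per_amplicon_mean):
            raise ValueError("amplicon means must be >= 0")


@dataclass
class ErrorModel:
    """Per-read base error: flat ``epsilon_base``, elevated in homopolymers.

    Errors are uniform over the three non-true bases; only the designated
    alternate allele counts as "alt", other error bases as "other".
    ``allelic_bias_sites`` maps a site position to the probability that a
    read from a heterozygote samples the alternate allele (default 0.5).
    """

    epsilon_base: float = 0.01
    epsilon_homopolymer: float = 0.05
    allelic_bias_sites: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon_base < 0.5:
            raise ValueError("epsilon_base must be in [0, 0.5)")
        if not self.epsilon_base <= self.epsilon_homopolymer < 0.5:
            raise ValueError("epsilon_homopolymer must be in [epsilon_base, 0.5)")
        for p in self.allelic_bias_sites.values():
            if not 0 <= p <= 1:
                raise ValueError("allelic-bias probabilities must be in [0, 1]")


@dataclass
class PileupSet:
    """Per-site per-sample (ref, alt, other) read counts, long form.

    ``frame`` columns: sample_id, pos (0-based), ref_count, alt_count,
    other_count.  Rows exist for every sequenced sample at every candidate
    site (truth-polymorphic sites, plus any site-sample with a non-reference
    read); uncovered site-samples simply have no row (depth 0).
    """

    frame: pd.DataFrame

    def site_matrix(self) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray, np.ndarray]:
        """Pivot to (positions, sample_ids, ref, alt, other) site x sample arrays."""
        samples = sorted(self.frame["sample_id"].unique())
        positions = np.sort(self.frame["pos"].unique())
        s_index = {s: i for i, s in enumerate(samples)}
        p_index = {p: i for i, p in enumerate(positions)}
        shape = (positions.size, len(samples))
        ref = np.zeros(shape, dtype=np.int32)
        alt = np.zeros(shape, dtype=np.int32)
        other = np.zeros(shape, dtype=np.int32)
        rows = self.frame
        pi = rows["pos"].map(p_index).to_numpy()
        si = rows["sample_id"].map(s_index).to_numpy()
        ref[pi, si] = rows["ref_count"].to_numpy()
        alt[pi, si] = rows["alt_count"].to_numpy()
        other[pi, si] = rows["other_count"].to_numpy()
        return positions, samples, ref, alt, other


def simulate_pileups(
    cohort: Cohort,
    region: RegionModel,
    depth_model: DepthModel | None = None,
    error_model: ErrorModel | None = None,
    seed: int = 0,
    statuses: tuple[str, ...] = (CASE,),
) -> PileupSet:
    """Simulate amplicon pileups for the sequenced individuals.

    Every base of the region is sequenced; depth follows the
    :class:`DepthModel`, each read reports its true allele with probability
    ``1 - epsilon(site)`` and otherwise one of the three other bases
    uniformly.  Heterozygote reads sample the alternate allele with the
    site's allelic-bias probability (0.5 unless configured).  Emitted rows
    cover all sequenced samples at truth-polymorphic sites plus any
    site-sample with at least one non-reference read elsewhere.
    """
    depth_model = depth_model or DepthModel()
    error_model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    pool = cohort.pool
    L = region.length_bp

    idx = np.concatenate([cohort.indices(s) for s in statuses]) if statuses else np.array([], int)
    idx = np.sort(idx)
    samples = [cohort.sample_ids[i] for i in idx]
    n = idx.size
    if n == 0:
        return PileupSet(frame=pd.DataFrame(columns=["sample_id", "pos", "ref_count", "alt_count", "other_count"]))

    positions = np.arange(L, dtype=np.int64)
    amp_idx = region.amplicon_index(positions)
    amp_mean = np.zeros(L)
    means = np.asarray(depth_model.per_amplicon_mean, dtype=float)
    covered = amp_idx >= 0
    amp_mean[covered] = means[np.minimum(amp_idx[covered], means.size - 1)]

    n_amp = len(region.amplicons)
    sig_s = depth_model.sample_scale_dispersion
    sample_amp = np.exp(rng.normal(-0.5 * sig_s**2, sig_s, size=(n, n_amp))) if sig_s > 0 else np.ones((n, n_amp))
    sig_t = depth_model.site_dispersion
    site_factor = np.exp(rng.normal(-0.5 * sig_t**2, sig_t, size=(L, n))) if sig_t > 0 else np.ones((L, n))

    lam = np.zeros((L, n))
    lam[covered] = amp_mean[covered, None] * sample_amp[:, amp_idx[covered]].T
    lam *= site_factor
    depth = rng.poisson(lam).astype(np.int32)

    eps = np.full(L, error_model.epsilon_base)
    eps[region.in_homopolymer(positions)] = error_model.epsilon_homopolymer

    # q_alt: probability a read is drawn from an alt-carrying chromosome
    q_alt = np.zeros((L, n))
    geno = cohort.genotype_matrix()[:, idx]  # (n_sites, n) dosage at pool sites
    bias = np.full(pool.n_sites, 0.5)
    for pos, p in error_model.allelic_bias_sites.items():
        j = np.searchsorted(pool.positions, pos)
        if j < pool.n_sites and pool.positions[j] == pos:
            bias[j] = p
    site_q = np.where(geno == 2, 1.0, np.where(geno == 1, bias[:, None], 0.0))
    q_alt[pool.positions] = site_q

    e = eps[:, None]
    p_alt = q_alt * (1 - e) + (1 - q_alt) * (e / 3.0)
    p_other = 2.0 * e / 3.0 * np.ones_like(q_alt)
    alt = rng.binomial(depth, p_alt).astype(np.int32)
    rest = depth - alt
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = np.where(p_alt < 1.0, p_other / (1.0 - p_alt), 0.0)
    other = rng.binomial(rest, np.clip(p_cond, 0.0, 1.0)).astype(np.int32)
    ref = rest - other

    truth_sites = np.zeros(L, dtype=bool)
    truth_sites[pool.positions] = True
    emit = (truth_sites[:, None] | (alt + other > 0)) & (depth > 0)
    pi, si = np.nonzero(emit)
    frame = pd.DataFrame(
        {
            "sample_id": np.array(samples, dtype=object)[si],
            "pos": positions[pi],
            "ref_count": ref[pi, si],
            "alt_count": alt[pi, si],
            "other_count": other[pi, si],
        }
    )
    frame = frame.sort_values(["pos", "sample_id"], kind="mergesort").reset_index(drop=True)
    return PileupSet(frame=frame)


# ---------------------------------------------------------------------------
# truth emission
# ---------------------------------------------------------------------------

@dataclass
class TrackConfig:
    """Controlled overlap structure for the synthetic annotation tracks.

    Fractions are of variant sites: ``dhsp_fraction`` of sites fall in a
    DHS peak (each assigned 1-2 cell-class codes), ``enhancer_fraction``
    in an enhancer element, and conserved elements (score > 2) cover
    ``conserved_in_dhsp`` of the DHSP-overlapping sites but only
    ``conserved_outside`` of the rest — the enrichment contrast the
    annotation stage measures.  Intervals are clipped so they contain no
    unchosen variant site, making the overlap fractions exact.
    """

    dhsp_fraction: float = 0.2
    enhancer_fraction: float = 0.15
    conserved_in_dhsp: float = 0.2
    conserved_outside: float = 0.03
    interval_halfwidth: int = 60


def _site_intervals(
    pool: HaplotypePool,
    chosen: np.ndarray,
    rng: np.random.Generator,
    L: int,
    halfwidth: int,
    namer,
    scorer=None,
) -> list:
    """One interval per chosen site, clipped to exclude neighbouring sites."""
    from .region import Interval

    out = []
    pos = pool.positions
    for j in np.sort(chosen):
        p = int(pos[j])
        left = int(pos[j - 1]) + 1 if j > 0 else 0
        right = int(pos[j + 1]) if j < pos.size - 1 else L
        w = int(rng.integers(halfwidth // 2, halfwidth + 1))
        start = max(p - w, left, 0)
        end = min(p + w + 1, right, L)
        score = scorer(rng) if scorer else None
        for name in namer(rng):
            out.append(Interval(start, end, name, score))
    return sorted(out, key=lambda iv: (iv.start, iv.name))


def emit_truth(
    cohort: Cohort,
    region: RegionModel,
    outdir,
    seed: int = 0,
    depth_model: DepthModel | None = None,
    error_model: ErrorModel | None = None,
    track_config: TrackConfig | None = None,
) -> dict:
    """Write the full synthetic truth bundle to ``outdir``.

    Files: case pileups (TSV), phased truth VCF for the sequenced cohort,
    array-truth VCF (the perfectly genotyped site subset), phased
    reference-panel VCF, a site-alleles table, the known-variant catalogue
    (reference-panel-polymorphic sites are "known"; case-private sites are
    therefore novel), a tag-SNP spec table, and three annotation tracks
    (DHSP, enhancer, conserved-with-score BED).  Deterministic under a
    fixed seed.
    """
    from pathlib import Path

    from . import io as hio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    track_config = track_config or TrackConfig()
    pool = cohort.pool
    rng = np.random.default_rng(seed)
    paths = {}

    # pileups for the sequenced (case) samples
    pileups = simulate_pileups(
        cohort, region, depth_model, error_model, seed=int(rng.integers(2**31 - 1))
    )
    paths["pileups"] = outdir / "pileups.tsv"
    hio.write_pileups(pileups.frame, paths["pileups"])

    seq_status = [s for s in (CASE, CONTROL) if cohort.indices(s).size]
    seq_idx = np.concatenate([cohort.indices(s) for s in seq_status]) if seq_status else np.array([], int)
    seq_idx = np.sort(seq_idx)
    seq_ids = [cohort.sample_ids[i] for i in seq_idx]
    haps_seq = pool.haplotypes[cohort.chrom_founders[seq_idx].reshape(-1)]

    paths["truth_vcf"] = outdir / "truth.vcf"
    hio.write_vcf(
        paths["truth_vcf"], pool.positions, pool.ref_bases, pool.alt_bases,
        seq_ids, haplotypes=haps_seq, contig_length=region.length_bp,
    )

    case_idx = cohort.indices(CASE)
    case_ids = [cohort.sample_ids[i] for i in case_idx]
    haps_case = pool.haplotypes[cohort.chrom_founders[case_idx].reshape(-1)]
    arr = cohort.array_truth_idx
    paths["array_truth_vcf"] = outdir / "array_truth.vcf"
    hio.write_vcf(
        paths["array_truth_vcf"], pool.positions[arr], pool.ref_bases[arr],
        pool.alt_bases[arr], case_ids, haplotypes=haps_case[:, arr],
        contig_length=region.length_bp,
    )

    ref_idx = cohort.indices(REFERENCE)
    ref_ids = [cohort.sample_ids[i] for i in ref_idx]
    haps_ref = pool.haplotypes[cohort.chrom_founders[ref_idx].reshape(-1)]
    paths["panel_vcf"] = outdir / "panel.vcf"
    hio.write_vcf(
        paths["panel_vcf"], pool.positions, pool.ref_bases, pool.alt_bases,
        ref_ids, haplotypes=haps_ref, contig_length=region.length_bp,
    )

    paths["sites"] = outdir / "sites.tsv"
    hio.write_sites_table(paths["sites"], pool.positions, pool.ref_bases, pool.alt_bases)

    # known = polymorphic among reference-panel chromosomes
    panel_alt = haps_ref.sum(axis=0)
    known_mask = (panel_alt > 0) & (panel_alt < haps_ref.shape[0])
    known_pos = pool.positions[known_mask]
    paths["catalogue"] = outdir / "catalogue.tsv"
    hio.write_catalogue(paths["catalogue"], known_pos)

    tag_lines = ["pos\trisk_allele\tprot_allele\n"]
    for k, j in enumerate(pool.tag_idx):
        tag_lines.append(
            f"{int(pool.positions[j]) + 1}\t{int(pool.risk_alleles[k])}\t{int(pool.prot_alleles[k])}\n"
        )
    paths["tags"] = outdir / "tags.tsv"
    hio.atomic_write_text(paths["tags"], "".join(tag_lines))

    # annotation tracks with controlled overlap
    S = pool.n_sites
    n_dhsp = int(round(track_config.dhsp_fraction * S))
    dhsp_sites = rng.choice(S, size=n_dhsp, replace=False) if n_dhsp else np.empty(0, int)
    n_enh = int(round(track_config.enhancer_fraction * S))
    enh_sites = rng.choice(S, size=n_enh, replace=False) if n_enh else np.empty(0, int)
    outside = np.setdiff1d(np.arange(S), dhsp_sites)
    n_cons_in = int(round(track_config.conserved_in_dhsp * dhsp_sites.size))
    n_cons_out = int(round(track_config.conserved_outside * outside.size))
    cons_sites = np.concatenate(
        [
            rng.choice(dhsp_sites, size=n_cons_in, replace=False) if n_cons_in else np.empty(0, int),
            rng.choice(outside, size=n_cons_out, replace=False) if n_cons_out else np.empty(0, int),
        ]
    ).astype(int)

    L = region.length_bp
    hw = track_config.interval_halfwidth
    dhsp_iv = _site_intervals(
        pool, dhsp_sites, rng, L, hw,
        namer=lambda r: sorted(r.choice(["1", "2", "3"], size=int(r.integers(1, 3)), replace=False)),
    )
    enh_iv = _site_intervals(
        pool, enh_sites, rng, L, hw,
        namer=lambda r: [str(r.choice(["NPC", "HSMM"]))],
    )
    cons_iv = _site_intervals(
        pool, cons_sites, rng, L, hw,
        namer=lambda r: ["CE"],
        scorer=lambda r: float(np.round(r.uniform(2.1, 6.0), 2)),
    )
    paths["dhsp_bed"] = outdir / "dhsp.bed"
    paths["enhancer_bed"] = outdir / "enhancer.bed"
    paths["conserved_bed"] = outdir / "conserved.bed"
    hio.write_bed(paths["dhsp_bed"], dhsp_iv)
    hio.write_bed(paths["enhancer_bed"], enh_iv)
    hio.write_bed(paths["conserved_bed"], cons_iv)
    return paths
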