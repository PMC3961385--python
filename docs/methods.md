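# Methods

This note documents the models behind `haploscan`, the defaults and their
rationale, what the synthetic generator does and does not emulate, and the
numerical conventions.

## Study design being modelled

A candidate-gene resequencing study: a gene locus of length L (default
95 kb at full scale, 10 kb in the test-scale geometry used throughout the
suite) is divided into eight long-range PCR amplicons plus one declared
un-amplifiable gap (a GC-rich promoter stretch). A small case cohort is
deep-sequenced across the region; genotypes are validated against an
orthogonal array-genotyped site subset; variant frequencies are compared
against a population reference panel (348 chromosomes by default); and
variants are interpreted on the background of two named haplotypes — a
"risk" and a "protective" pattern over six tag SNPs — with everything else
labelled "other".

## Synthetic generator

**Founder pool.** Background variation is placed on single-population
Kingman coalescent genealogies over the founder chromosomes, simulated
with msprime (haploid samples, pairwise coalescence rate 1) and mutated
under an infinite-sites scheme at per-site rate θ/2 per unit time, so the
expected segregating-site count among n founders is exactly
`E[S] = θ · L · a_n`, `a_n = Σ_{i<n} 1/i` — the quantity Watterson's
estimator inverts. Continuous mutation positions are floored to unique
integers. The `n_blocks` option splits the region into independent
genealogical stretches: the mean of S is unchanged while the
single-tree variance component shrinks by `1/n_blocks`. One block is the
classical single-locus model; the stratified pool defaults to ten blocks,
which is both closer to a multi-kilobase region with recombination and
necessary for per-replicate ordering statements about class-stratified
diversity (a single tree's height variance gives S a coefficient of
variation of ~30–40% that no amount of sequence length removes).

Founders are partitioned into RISK/PROT/OTHER groups and their six tag
sites overwritten with the class patterns (OTHER founders get random
patterns distinct from both). Default class frequencies (0.365, 0.121,
0.514) mirror a reference panel in which 127 and 42 of 348 chromosomes
carry the risk and protective backgrounds. Founder frequencies are a
within-class Dirichlet(1) split — the frequency spectrum of "other"
backgrounds is not a quantity the design pins down, so it is exposed as
configuration rather than fixed.

**Cohort.** Each chromosome of each individual is an independent draw
from the founder frequencies. Case draws use class-odds-shifted
frequencies: for a configured odds ratio R on class c with base
probability p, the case probability is `p' = Rp/(1−p+Rp)` with the other
classes rescaled proportionally, so the class-indicator odds ratio between
case and control chromosomes is exactly R. The default case shift is
R = 1.3 on the risk class, the value implied by 40/94 case chromosomes vs
127/348 panel chromosomes. The array-truth subset is a random half of the
sites common in the pool (population frequency in [0.05, 0.95]), always
including the six tags.

**Depth.** Site depth for sample i is Poisson with mean
`amplicon mean × lognormal(sample × amplicon) × lognormal(site)`; both
lognormal factors are mean-one with σ of 0.5 and 0.3. This reproduces the
blocky amplicon-by-sample structure of pooled amplicon libraries.
Default amplicon means (25, 32, 18, 22, 35, 30, 12, 24) are heterogeneous
with every mean above 10, the depth regarded as sufficient for diploid
genotyping. Gap sites get depth 0.

**Errors.** Each read reports its true allele with probability `1 − ε`
and otherwise one of the three other bases uniformly; ε is 0.01 baseline
and 0.05 inside declared homopolymer intervals (pyrosequencing-style
context-dependent error). Heterozygote reads sample the alternate
chromosome with probability 0.5 unless a site is configured with PCR
allelic bias. Only the designated alternate base counts as "alt"; other
error bases count as "other" and cancel out of the genotype likelihood
ratios.

**What the generator does not emulate.** Read-level artefacts (mapping
error, indels, strand effects), linkage between depth and sequence
context beyond the homopolymer map, population structure in the panel,
and relatedness. Passing tests therefore demonstrate correctness of the
analysis given the stated error model, not robustness to every real-data
pathology.

## Genotype caller

Per-read symmetric-error biallelic likelihoods (see README for the three
genotype formulas). The caller's ε is a flat 0.01 and is deliberately not
informed by the simulator's homopolymer map — the mismatch between the
assumed and true error model is part of what the filters are for.

Cohort allele frequency is estimated per site by EM over the diploid HWE
mixture of the per-sample likelihood triples (initial value 0.05,
convergence |Δaf| < 1e-6 or 100 iterations, vectorised across sites).
Calls are maximum posterior under the HWE prior at the estimated
frequency; posterior ties break toward fewer alternate alleles
(conservative toward reference). Site QUAL is the phred-scaled
probability that no sample carries an alternate allele
(`Σ_i −10·log10 P_i(hom-ref)` over samples with data), and QD divides
QUAL by the summed depth of samples called non-reference.

GQ is likelihood-based: the second-smallest normalised PL, capped at 99 —
the phred gap between the best and second-best genotype, i.e. a
likelihood-ratio confidence. Posteriors influence the call and the site
QUAL but not GQ, keeping the invariant GQ = second-smallest PL exact.

Hard filters: QD < 5.0 (strictly less fails; the stricter of the two
conventional thresholds, chosen because low-QD/high-AF calls are
characteristically spurious), FS > 60, rank-sum analog < −8. With no
alignment layer there is no mapping quality or haplotype score; those
threshold keys are accepted in configuration but inert, by declaration
rather than silent omission. The FS analog is a phred-scaled two-sided
binomial allele-balance test over pooled reads of het-called samples —
it is what flags PCR allelic-bias sites in this pipeline — and the
rank-sum analog compares ref vs alt read counts across het samples.

The naive caller (alt reads ≥ 3, alt fraction ≥ 0.2 for non-reference,
≥ 0.8 for hom-alt, per sample independently) stands in for a
vendor-style per-sample threshold caller whose internals are not public;
its role is to generate an independent call set for the consensus codes,
not to be accurate.

## Concordance

Discordance compares unphased genotype classes. Accuracy excludes
missing/GQ-filtered calls; the call rate counts them against the truth
genotypes present — the denominator is sites present in the truth set
(whether it should include truth-missing sites is not determinable from
the design; this choice is documented here). The outlier threshold
defaults to 0.25 per-sample discordance, midway between a swapped or
contaminated sample (~50%) and the bulk error level (~2%).

## Frequency comparison and association

Minor alleles are oriented within the case cohort; the reference
frequency is reported for the same allele, with a warning flag when the
panel's own minor allele differs. The allelic test is the Pearson χ²
closed form `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` with p from the χ²(1)
survival function; degenerate margins return (0, 1). OR confidence
intervals are Wald on the log scale; zero cells get Haldane–Anscombe
+0.5 for OR/CI only (flagged), never for the χ². QC removes samples with
missingness strictly above 10% first, then variants with MAF strictly
below 5% recomputed on the remaining samples. The Bonferroni helper
defaults to 11 tests (the worked-example condition); the pipeline's
association stage corrects for the number of variants it actually tests.

Common-variant completeness is measured over panel variants with
MAF ≥ 0.1. Panel variants falling inside the declared amplification gap
cannot be detected by sequencing, so completeness on the synthetic
fixture is usually 1.0 but occasionally below — the synthetic analogue of
platform-inaccessible sites.

## Haplotype analysis

Classification is strict all-six matching of the tag alleles (a
chromosome matching five of six is OTHER; any unknown tag allele is ND).
Watterson's θ is computed per class from sites polymorphic within that
class's chromosomes only; classes with fewer than two chromosomes are
skipped. Exclusivity codes per variant: on each axis, 2 = every
minor-allele carrier belongs to the class, 1 = carriers include the class
and others, 0 = no carrier in the class, ND = any carrier unphased (the
"0 vs 1 both mean non-exclusive" ambiguity is resolved exactly this way,
and the convention is written into the output header). The segregation
scan requires ≥ 1 carrier in one named class and 0 in the other, ignoring
OTHER carriers; ND chromosomes are excluded from the scan. Tagging is
r² ≥ 1 (configurable) against a named tag SNP on phased panel haplotypes.

Phasing uses a windowed Excoffier–Slatkin EM: within each window of
(default) five sites, haplotype frequencies are estimated by EM over the
enumeration of genotype-compatible diplotypes, with reference-panel
haplotypes counted as observed chromosomes; windows overlap by half and
are stitched by majority agreement over the overlap. Samples with
EM-tied diplotypes, all-het uninformative windows or unresolvable
stitching are flagged uncertain. The pipeline's default path feeds the
simulator's phased truth straight through; the EM exists for unphased
input and is validated on panel-resolvable fixtures and high-LD cohorts.
Recombination-aware (Li–Stephens) phasing and imputation of untyped sites
are out of scope at region scale.

## Annotation

Interval membership is half-open point-in-interval. A constraint score is
attached only when the variant lies inside a conserved element; variants
outside elements have no score and are never "conserved" (score > 2).
The "frequency difference ≥ 0.05" clause of the candidate-selection
criteria uses the absolute value. Multi-library peak clustering is
emulated by a breakpoint-sweep merge keeping stretches supported by ≥ 2
libraries.

## Problem sizes and determinism

The default fixture is the 10 kb test-scale region with 48 cases and a
174-individual panel at θ = 5.42×10⁻⁴ — small enough that the full
chain runs in seconds while every downstream stage sees realistic
structure; the full-scale 95 kb geometry is available via configuration.
Replicate counts in the validation experiments (200 for estimator
recovery, 50 for the ordering experiment, 20 for filter monotonicity,
≥ 1000 for null calibration) were chosen to make the Monte-Carlo error a
small fraction of the tested effect. All randomness flows from a single
integer seed; a rerun with the same seed reproduces every artefact
byte-for-byte, and all writers are atomic.

## Known limitations

- SNVs only; indels and multi-allelic sites are out of scope.
- No read-level alignment layer, hence no true mapping-quality or strand
  filters; their analogs are allele-balance based.
- The naive caller is a plausible stand-in, not a reverse-engineered
  vendor algorithm; dual-caller set sizes on synthetic data are
  structurally, not numerically, comparable to real tool pairs.
- Real-data θ values, concordance rates and flagged-variant counts from
  the motivating study design depend on unavailable raw sequence; the
  package reproduces their printed-input computations and validates the
  corresponding estimators by parameter recovery instead.
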