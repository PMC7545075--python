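# Methods

This note documents the statistical models behind `gallipop`, the defaults
and why they were chosen, what the bundled simulator does and does not
emulate, and the numerical conventions that affect results.

## Data model and quality control

Genotypes are diploid biallelic alt-allele dosages in {0, 1, 2} with a
missing code, carried with 1-based physical coordinates and per-sample
population and sex labels. QC removes variants — never samples — when the
minor allele frequency falls below 0.05, the call rate below 0.90, or an
exact Hardy–Weinberg test rejects at p < 1e-6. The HWE test is the
conditional exact test on heterozygote counts given the allele counts
(plain p, not mid-p), the convention of standard array-QC toolkits. All
three statistics are computed on the pooled sample by default (a
per-population mode exists but is not the default), and sex-linked variants
are exempt from the HWE filter because hemizygosity in the heterogametic
sex violates its assumptions. Removal reasons are reported with precedence
MAF → call rate → HWE so each removed variant carries exactly one reason;
the retained set is order-independent and the filter is idempotent.

## Diversity statistics

Observed heterozygosity is per individual: heterozygous calls over
non-missing calls. Expected heterozygosity uses the unbiased per-locus
estimator 2p̂(1−p̂)·N/(N−1) on the allele basis N (twice the number of
non-missing genotypes), averaged over loci. Nucleotide diversity over the
ascertained SNP sites is π = n_ref·n_alt / C(N,2) per site — algebraically
the same estimator as unbiased expected heterozygosity, reported separately
because the two are averaged and summarised differently downstream. π here
is per SNP site, not per base pair; no genome-length normalisation is
applied. The summary table reports the SD of He across SNPs (labelled as
such); at array scale this rounds to 0.00, which is why published tables of
this statistic show ±0.00.

## FST

Pairwise differentiation uses the full two-population Weir–Cockerham (1984)
estimator with all three variance components a (between populations), b
(between individuals within populations) and c (within individuals,
the observed-heterozygosity term), accumulated over loci as
Σa / Σ(a+b+c). Loci monomorphic across both samples are excluded
(zero denominator). The estimator is *not* truncated: small negative
multi-locus estimates are legitimate sampling outcomes of an unbiased
estimator near FST = 0, and truncation would bias averages. The four-level
classification assigns value < 0.05 → low (negatives included),
[0.05, 0.15) → medium, [0.15, 0.25] → high, > 0.25 → extreme; the
interval endpoints are assigned explicitly because verbal range
descriptions are ambiguous at the boundaries.

## Linkage disequilibrium

r² is computed from haplotype frequencies, not genotype correlations:
r² = (p_AB·p_ab − p_Ab·p_aB)² / (P_A·P_a·P_B·P_b). Because input genotypes
are unphased, haplotype frequencies are estimated per locus pair by the
standard two-locus EM algorithm: all cells of the 3×3 genotype table except
the double heterozygote resolve phase deterministically; the double
heterozygote's AB/ab versus Ab/aB split is the E-step expectation. EM
starts from linkage equilibrium and stops when the largest frequency change
drops below 1e-10 or after 1,000 iterations. The all-double-heterozygote
table has a symmetric likelihood with two equal modes; the linkage-
equilibrium stationary point (D = 0) is reported and flagged as degenerate.
The EM is vectorised across pairs, which is what makes genome-scale decay
curves and the unlinked-pair Ne estimator affordable.

Decay curves use all intra-chromosomal autosomal pairs closer than 500 kb,
binned into half-open (start, end] bins of 5 kb, on a seeded subsample of
7 individuals per population (the subsample size used by small-sample LD
surveys; both the size and seed are recorded in the output). "Evaluating at
5 kb" rather than binning is available by setting the bin width to 1 bp.
Sex-linked SNPs are excluded (mixed ploidy).

## Effective population size

Physical distance maps to recombination fraction linearly (default
1 cM/Mb, capped at c = 0.5); a per-chromosome rate can be supplied.

*Historical trajectory.* Pairs are binned by c; each bin is inverted
through the Sved relation E[r²_adj] = 1/(α + 4Nc), giving
Ne = (1/(4c̄))(1/E[r²_adj] − α) at t = 1/(2c̄) generations ago. α = 1 is
the drift-only default; α = 2.2 (mutation-adjusted) is a flag. Bins with
fewer pairs than a threshold are masked. The inversion is exact by
construction when each bin holds a single c — this self-inverse property is
a test invariant.

*Contemporary point estimate.* At effectively unlinked pairs (different
chromosomes or c ≥ 0.1), E[r²] ≈ 1/(3Ne) + 1/S for S diploids with
EM-based unphased r², so N̂e = 1/(3(mean r² − 1/S)). The sample-size term
is 1/S, not 1/(2S), because r² comes from unphased EM estimates. When
mean r² ≤ 1/S the estimate is reported as undefined (consistent with
infinite Ne), never as a negative number. Individuals are subsampled
(seeded) to 40 by default, matching common practice for this estimator.
Numeric parity with the dedicated tools' additional small-sample bias
polynomials is not claimed; validation is against simulator ground truth
(median recovery of N = 50 from S = 40 within the test tolerance).

## Runs of homozygosity

Detection reproduces the scanning-window semantics of the classic
array-based callers. Stage 1: a 50-SNP window slides along each autosome; a
window passes with ≤ 1 heterozygote and ≤ 5 missing calls; each SNP's hit
proportion is passing windows overlapping it over windows overlapping it,
and SNPs at proportion ≥ 0.05 become candidates. Stage 2: maximal candidate
runs are split at inter-SNP gaps > 1,000 kb and kept if ≥ 100 kb long,
≥ 25 SNPs, and at most 50 kb/SNP. The window-stage allowance means final
segments can contain isolated heterozygous or missing calls — deliberate,
as it matches the reference tool. The hit threshold (0.05) and minimum
segment SNP count (25) are the reference tool's defaults for the two
parameters the published settings leave unstated; without the 25-SNP floor
the 100 kb / 50 kb-per-SNP settings would admit 2-SNP segments. Both are
exposed in `ROHParams`. A brute-force nested-loop scanner implementing the
same contract serves as the equivalence oracle in tests.

F_ROH = Σ L_ROH / L_AUTO with L_AUTO defaulting to 952,090 kb (the
autosomal span typed by the 600K chicken array); for other inputs it is
recomputed as the summed per-autosome span of typed SNPs. Per-SNP ROH
incidence is the fraction of a group's individuals with a ROH covering the
SNP; island calling selects SNPs at or above the empirical 99th percentile
of incidence (and above zero) and merges adjacent selected SNPs on a
chromosome. When every SNP ties at the threshold the degenerate result is
one island per chromosome, which is reported rather than suppressed.

## Effective sex ratio

Drift since divergence is summarised per marker class by the branch length
τ = t/(2Ne) on the diffusion time scale. With
Ne(A) = 4N_fN_m/(N_f+N_m) and Ne(X) = 9N_fN_m/(2N_f+4N_m) (homogametic
females carrying two copies), the conversion

ε = 2 − (9/8)·τ(X)/τ(A)

is algebraically identical to ε = N_f/(N_f+N_m), the proportion of females
in the effective population — an identity the test suite checks on a grid.
The balanced ratio τ(X)/τ(A) = 4/3 gives ε = 1/2 exactly. Applied to Z
data under ZW heterogamety (birds), the same arithmetic yields the
proportion of *males*; the package evaluates the formula as printed and a
`heterogamety` flag controls only the interpretation label, never the
arithmetic. The Z-linked effective size under ZW is the mirror image,
Ne(Z) = 9N_fN_m/(2N_m+4N_f); both forms were verified against a direct
transmission-level drift simulation.

*Moment estimator.* Per SNP, [(p̂−π)² − p̂(1−p̂)/(n_chrom−1)] / (π(1−π))
estimates the standardised drift variance F, where π is the ancestral (or
pooled-reference) frequency and n_chrom the class-specific chromosome count
(2n autosomal; 2n_homogametic + n_heterogametic on the sex chromosome,
where hemizygous array calls contribute half their dosage and one
chromosome). The noise term is divided by n_chrom − 1, which makes its
expectation exactly the binomial sampling variance p(1−p)/n_chrom. The mean
F̂ is mapped to the diffusion scale by τ = −log(1−F̂), exact for pure
Wright–Fisher drift where F = 1 − (1−1/(2Ne))^t; without this transform τ
ratios are biased once drift is no longer small (at τ(A) = 0.25 the raw
ratio would shift ε by ≈ +0.05). SNPs with π ∈ {0, 1} are excluded.

*Hierarchical Bayesian estimator.* The time-dependent drift diffusion is
approximated by a truncated normal (Nicholson model):
p_pop ~ TN(π, τ·π(1−π)) on [0, 1], observed counts binomial, π uniform, τ
log-uniform, populations sharing π on a star tree. Sampling is random-walk
Metropolis, vectorised across SNPs, with pilot-run step adaptation
targeting acceptance in (0.25, 0.45) and a thinned post-burn-in chain. The
truncated-normal likelihood is the key approximation: it is accurate in the
small-to-moderate τ regime these analyses operate in but lacks the point
masses at fixation of the exact diffusion, so it will understate τ for
extremely drifted data. The moment and MCMC estimators are cross-checked
against each other on model-generated data in the tests.

*Pseudo-replication.* Replicate SNP panels (default 50 replicates of 5,000
autosomal + 5,000 sex-linked SNPs, seeded, sampled with replacement only
when the input is smaller, with a warning) each yield (τ_A, τ_sex, ε); the
per-replicate distribution is reported unclamped — out-of-range ε values
are flagged, not truncated, so replicate spreads remain honest. When sexes
are unrecorded, the heterogametic sex is inferred from near-zero sex-
chromosome heterozygosity (arrays call hemizygotes as homozygous), with a
warning.

*Validation scenarios.* Panels resampled from one simulated genome share
that genome's drift realisation: drift correlation between linked SNPs
decays on a map scale of roughly 1/t Morgans, so a 50-generation history
leaves only ~100 independent drift blocks on an 80 Mb, 3 cM/Mb sex
chromosome and the per-genome SD of ε is ≈ 0.15 no matter how many SNPs
are typed. The recovery experiments therefore pseudo-replicate across
independent simulated datasets (default 10) and average, which reduces the
error of the mean to ≈ 0.05. The validation genome is chicken-like — five
100-Mb autosomes and an 80-Mb sex chromosome at 3 cM/Mb, 5,000 SNPs per
class — and retains sites fixed by drift (no array ascertainment), because
the estimator references the known ancestral frequencies and conditioning
sites on final-sample segregation was measured (by an unlinked-locus
oracle) to bias ε by about −0.03.

## Population structure

The GRM is G_jk = mean over polymorphic autosomal SNPs of
(x_j−2p)(x_k−2p)/(2p(1−p)) with pairwise-complete missing-data handling
(per-pair SNP intersection, not mean imputation). PCA is the
eigendecomposition of G; coordinates are eigenvectors scaled by the square
root of their eigenvalues, variance proportions are eigenvalues over the
trace, and the sign convention makes each component's largest-magnitude
loading positive. Note that with sample-estimated frequencies the GRM
off-diagonals of unrelated individuals centre on −1/(n−1), not 0.

Trees are Saitou–Nei neighbor joining on 1 − IBS distances (IBS per pair:
1 − |dosage difference|/2 averaged over shared non-missing SNPs), at
individual or population level (mean inter-population individual distance).
Q-criterion ties break on the lexicographically lowest label pair, making
topologies deterministic; negative NJ branch lengths are preserved and
flagged. NJ exactly recovers additive distance matrices (tested against
random trees and cross-checked against an independent library
implementation); newick output carries full-precision branch lengths.

## The simulator

A forward-in-time discrete-generation two-sex Wright–Fisher model:
constant census of N_f dams and N_m sires per population, offspring drawing
a dam and sire per the mating scheme (`random`; `half_sib` concentrates
sirings in ⌈N_m/5⌉ males; `full_sib` maintains closed dam–sire family
lines), autosomal gametes formed with Poisson crossover counts on a linear
map, and a sex chromosome following ZW (dams pass their single Z to sons;
sires pass a recombinant Z to all offspring) or XY semantics. Hemizygous
genotypes are emitted as homozygous diploid calls, as arrays report them.
Forward simulation (rather than coalescent) is required because ROH,
pedigree inbreeding and sex-specific transmission are the targets;
practical scales are ≤ 200 diploids × ≤ 300 generations × ≤ 20k SNPs.

Founders draw alleles Bernoulli(q) from ancestral frequencies
q ~ Uniform(0.05, 0.95) (the standing-variation spectrum an array would
ascertain), at linkage equilibrium. "t generations since the common
ancestor" counts the founder draw as drift generation 1 — with equal sex
numbers its variance is exactly 1/(2Ne) on both marker classes — followed
by t−1 breeding rounds, so E[FST] = 1 − (1−1/(2Ne))^t holds without an
off-by-one. t = 0 emits founders directly (residual ~1/(2N) noise).
Mutation is off by default so drift-only closed forms stay exact. By
default, sites fixed in the final combined sample are dropped, mimicking
array polymorphism ascertainment (this depresses He/π and, if ancestral
frequencies are used as reference, biases drift contrasts — which is why
the ESR validation scenarios disable it). Ground truth records census
sizes by sex, true ε, Ne(A) and Ne(sex), divergence time, the pure-drift
FST expectation, and pedigree mean inbreeding per generation from an exact
kinship-matrix recursion.

What the simulator does not emulate: mutation–drift equilibrium (founders
carry array-like standing variation instead), selection, migration after
divergence, overlapping generations, genotyping error, and real chicken
demography or karyotype (39 autosome pairs; the scenarios use a handful of
macro-chromosome-sized autosomes). Passing recovery tests therefore shows
estimator correctness under idealised drift, sampling and transmission —
not robustness to selection, admixture or call errors in real data.

## Reproducibility conventions

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from the global seed by a labelled SHA-256 hash so stages
can be rerun in isolation. Pipeline outputs are byte-identical for
identical (input, config, seed) and are stamped with the package version,
a config hash and the stage seeds. Coordinates are 1-based inclusive at
all interfaces (VCF convention); BED export converts to 0-based half-open.

## Problem sizes used in the bundled validation experiments

FST recovery: two populations of 50+50 diverging 20 generations, 5,000
unlinked-ish loci on 10 chromosomes, 10 replicate simulations, median
compared at ±15%. Contemporary Ne: N = 50 (25+25), S = 40, 20 generations,
10 replicates, median at ±50%. ESR: 10 replicate datasets of the
chicken-like genome above, mean ε compared at ±0.1. ROH: exact equivalence
with the brute-force oracle on 1,000 random single-chromosome genomes of
up to 500 SNPs. HWE: exact-rational enumeration for every genotype triple
with total ≤ 50 at 1e-12. These sizes were chosen so the whole validation
suite completes on a single CPU in a few minutes while leaving each
assertion statistically meaningful.
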