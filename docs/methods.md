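# Methods

## Model

A biallelic locus with parental allele frequency p acts additively on a
quantitative trait. Parents are assumed unrelated, non-inbred, and in
Hardy–Weinberg proportions; the F1 offspring of a pair cross are
intercrossed at random, so the resulting F2 family segregates at the mean
parental allele frequency. The family's locus content is the union of the
four parental allele copies: the pool allele frequency g_F2 = k/4 with dose
k ~ Binomial(4, p). Equivalently, the six parental mating classes
(aa×aa … AA×AA, frequencies (1−p)^4, 4p(1−p)^3, 2p²(1−p)², 4p²(1−p)²,
4p³(1−p), p^4) map onto the five pool frequencies; `mating_table` and
`pool_genotype_probs` are tested against each other as an algebraic
identity.

The family phenotype is the family mean, P = μ + b·g_F2 + e with
e ~ N(0, σ_e²). The slope per unit pool frequency is b = 2a, twice the
allele-substitution effect, and the genetic variance across pools is
p(1−p)a² — half the individual-scale 2p(1−p)a², because each parent
contributes the variance of half a diploid genotype. Inbreeding in the F2
generation is ignorable here: it redistributes variance within families but
leaves family means unchanged under additivity. Dominance, parental
relatedness and selection/drift distortions are out of scope.

**Effect parameterization.** The public API takes b, the quantity the
regression estimates; a = b/2 is derived. The package's reference explained
variances (0.0014, 0.0032, 0.0039 at p = 0.1, 0.3, 0.5 with σ_e = 4) are on
this scale with b = 1, via V_g/(V_g + σ_e²), V_g = b²p(1−p)/4. The third
value is 0.003891; a truncated 0.0038 is accepted by the tests within
±0.0001.

## Measurement error and correction

Sequencing a pool to total depth S_T gives ĝ_F2 = S1/S_T with conditional
variance g(1−g)/S_T. Averaged over the five pool genotypes this is
σ²_bin = 3p(1−p)/(4 S_T), and the population OLS slope becomes
b·var(g)/(var(g)+σ²_bin) = b/(1+3/S_T): the allele frequency cancels, so
the attenuation depends on depth alone. `correct_attenuation` divides the
fitted slope and its standard error by this factor (a first-order,
delta-method treatment); the p-value is reported from the uncorrected fit,
since significance is invariant to rescaling slope and SE together.

For variable depth the package uses a single dataset-wide plain harmonic
mean over families with nonzero depth (each family weighted equally);
zero-depth families are dropped and counted, never imputed. The harmonic
mean is the right average because the noise variance is additive in 1/S_T
per family.

## Simulator

`simulate_dataset` emulates one SNP of a pooled GBS experiment: pool
frequencies from Binomial(4, p)/4; Gaussian phenotypes; depth either
constant or Poisson(λ) with zeros kept as missing records (matching the
e^(−λ) missing-data rate: 0.7 %, 0.2 %, 0.1 % at λ = 5, 6, 7); reads
Binomial(S_T, g′) where g′ = g(1−ε) + (1−g)ε folds a symmetric per-read
error ε into the success probability — distributionally identical to
flipping reads individually, at a fraction of the cost. Hard genotype
calling is modelled as rounding ĝ to the nearest quarter, midpoints rounding
up (a deterministic tie-break; maximum-likelihood calling is not modelled).
Two-locus mode draws four haplotypes per family from frequencies
x11 = p1q1+D, x12 = p1q2−D, x21 = p2q1−D, x22 = p2q2+D with
D = r√(p1p2q1q2); the haplotype-level correlation r propagates unchanged to
the pool frequencies. An infeasible r (any x < 0) raises rather than clips,
so a study never silently runs at a different LD than requested.

What the simulator does *not* model: read-level base quality and Phred QC,
alignment and SNP-calling artefacts, multi-SNP genomes and genome-wide LD
structure, overdispersed (non-Poisson) coverage, and library-preparation
biases that make real pool frequencies non-binomial. Passing tests
demonstrate internal consistency of estimator and theory under binomial
sampling, not robustness to those real-data features.

## Power engine

`run_power` simulates the full chain per replicate and counts slope t-tests
with p < α (two-sided, α = 0.05 by default; the degrees of freedom are
n_used − 2). Replicate i of design j draws from the dedicated substream
SeedSequence((master_seed, j, i)): deterministic given the master seed,
independent across replicates, and designs can share random numbers by
sharing j. Monte-Carlo uncertainty is reported as √(power(1−power)/reps).

Design grids: the fixed-budget preset compares (4000 families × depth 3),
(2000 × 7), (1000 × 15), (500 × 30) — efforts 12,000–15,000 read-families,
accepted within ±25 % of the nominal budget. The LD preset at n = 2000
pairs r = 0.95/0.7/0.3 with depths 7/15/30 (halving SNP density buys a
doubling of depth) for σ_e ∈ {2, 4} and p ∈ {0.1, 0.3, 0.5}, plus a
causal-locus design per cell; the causal locus is sequenced at depth 7 by
default — the depth is a free parameter, as no canonical choice exists.
Both loci in two-locus mode share the same allele frequency, which keeps
r = 0.95 feasible at every p used. The error-stacking study runs each
design under Poisson depth with three noise layers: binomial sampling only,
plus 10 % per-read error, plus genotype calling; power decreases weakly
across layers.

## Numerical choices and problem sizes

The binomial pmf for n = 4 is evaluated as an explicit polynomial (exact
and stable for p at the extremes). OLS uses `scipy.stats.linregress`.
Datasets round-trip losslessly through TSV (`%.17g` floats, round-trip
parsing). Distribution identities are tested at 1e−12, the LD round-trip at
1e−9. Stochastic checks run at n = 10⁵ draws with 3-standard-error bounds;
the attenuation-law and power acceptance checks use 1000 replicates at
n = 4000 and n = 2000 respectively, the sizes at which replicate means are
stable to ~1 % while the whole suite stays interactive.

## Known limitations

- The attenuation correction is first-order; its SE treatment ignores the
  uncertainty of the bias factor itself (depth is treated as known).
- Single-SNP inference only: no multiple-testing control, kinship
  correction, or multi-locus weighting (the bias factors would be natural
  per-SNP weights in such models).
- One reference two-locus power value used by the acceptance tests
  (σ_e = 2, p = 0.1, r = 0.95, depth 7: power 0.696) sits ~0.06 below what
  both this simulator and an independent normal-approximation power
  calculation give; the neighbouring grid cells agree closely under both
  checks.
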