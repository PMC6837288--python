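# Methods

This note documents the models, estimators, numerical choices, and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Per-site statistics

**Weir–Cockerham θ.** The two-population variance components a, b, c are
computed per site from diploid sample sizes, alternate-allele counts and
heterozygote counts; θ̂ = a/(a+b+c) is undefined (NaN) when the pair is
monomorphic (zero denominator). Missing genotypes are dropped per site per
population; a site enters the scan when every population has at least one
called diploid and per-population missingness is at most 50% (configurable).
The multi-site summary reports the mean ± SEM of per-site θ̂ as the
headline (matching the way such values are usually printed) and the
ratio-of-sums estimator Σa/Σ(a+b+c) as a secondary output.

**PBS.** Branch lengths use T = −ln(1 − F<sub>ST</sub>) with per-site
estimates floored at 0 and capped at 1 − 1e-12 (the transform diverges at
1; selection scans conventionally floor negative F<sub>ST</sub>). PBS
itself is never floored: negative values are legitimate draws of the null
and are retained. Estimator output slightly above 1 (possible because the
b component can be negative) is clamped; user-supplied F<sub>ST</sub>
above 1 is an error.

**HWE exact test** follows Levene's conditional distribution of
heterozygote counts given allele counts, summing probabilities ≤ that of
the observed count (standard, not mid-p). **Quantile thresholds** use the
left-continuous empirical-CDF convention: the smallest observed value v
with ecdf(v) ≥ q. **LD** is the squared Pearson correlation of dosages
over pairwise-complete samples, undefined for monomorphic sites.

## Structured coalescent

Time is continuous, in generations; deme sizes are diploid; pairwise
coalescence occurs at rate 1/(2N) per generation within a deme. Migration
is parameterized as diploid migrant individuals per generation between a
deme pair (N·m), so the backward per-lineage hop rate out of deme i is
M_ij/N_i. Splits are instantaneous lineage merges looking backward; after
the last split the remaining deme takes the ancestral size. Two genome-wide
migration-rate classes are supported; each locus draws its class
Bernoulli(P).

Each locus is one independent genealogy carrying exactly one segregating
site (a mutation placed on a branch chosen proportionally to length — ms
`-s 1` semantics, no recombination). This fixed-S ascertainment weights
genealogies uniformly rather than by total length and therefore enriches
singletons relative to the Poisson-mutation 1/i law; the test suite
asserts both the enrichment and the fact that length-weighted draws
recover 1/i. Null PBS distributions pair haplotypes randomly into diploids
and use the same Weir–Cockerham estimator as the empirical scan (Hudson's
estimator is available as an option).

For the two-deme island model the estimator target has the closed form
F<sub>ST</sub> = 1/(1 + 8Nm) (T_within = 4N, T_between = 4N + 1/(2m));
this, the 1/i spectrum, and a total-variation comparison of the folded
2D-SFS against msprime are the simulator's validity checks.

The inner event loop is compiled with numba; 10⁴ genealogies of ~30
lineages take on the order of 0.05 s, which is what makes Monte-Carlo
composite-likelihood fitting practical.

## Three-population null model

The stitched null model places the highland deme on the persisting lineage:
the first lowland deme splits from it at the older time, the second at the
younger; the two lowland demes exchange no direct migrants. The published
per-deme sizes are used as constant daughter sizes. Two quantities are not
derivable from the published numbers and are fixed by package choice:

* the ancestral size, set to the highland lineage's size (that lineage
  persists through both splits);
* "migrants/generation" is interpreted as diploid migrant individuals per
  generation (N·m), consistent with the calibration convention below.

A reproducibility caveat, measured by the acceptance suite: under these
printed parameters the 99.9th percentile of the simulated PBS null is
dominated entirely by the low-migration locus class and lands far above
the published simulated threshold, while a high-class-only run lands close
to it. The package simulates what the stated model implies and reports the
honestly computed value; the discrepancy (the source of which cannot be
resolved from the published description, which itself prints two different
thresholds) is asserted as an expected failure in the acceptance test.

## Demographic inference

The observed folded 2D-SFS drops sites with >25% missing data per
population, projects each site down to a target haploid sample size with
hypergeometric weights (fractional cell counts are allowed; log-factorials
use the log-gamma function), and folds onto minor-allele counts with a
lexicographic tie-break on the fold line.

The composite likelihood treats unmasked cells as independent Poisson
counts with mean θ·ê, where ê is the Monte-Carlo expected spectrum
(branch-length accumulator — the Rao-Blackwellized form of one-mutation
sampling) and θ is profiled analytically (θ̂ = Σn/Σê). Model families for
a two-deme split: `no_mig` (ν₁, ν₂, T), `one_mig` (+M), `two_mig_classes`
(M_high, M_low, P). Units follow the diffusion-method convention: ν
relative to the ancestral size, T in 2N_anc generations, M = 2N_anc·m;
calibration gives N_anc = θ/(4μL), times in generations = 2N_anc·T, and
migrants/generation = M/2. Default parameter bounds mirror the published
uniform priors (2Nm ∈ (0,10), 2Nt ∈ (0.01,10), size ratios (0.1,10),
P ∈ (0.5,1)).

### Monte-Carlo noise control

A noisy expected spectrum biases n·ln(ê) downward, more strongly for
sparsely-hit cells, which in practice pushes fits toward models whose
small cells happen to be better resolved. Three defenses are built in:

* **Common random numbers**: within a restart every likelihood evaluation
  reuses one random stream, making the objective deterministic and locally
  smooth.
* **First-order bias correction**: the per-cell squared relative MC
  standard error is tracked and n·relvar/2 (capped at n/2) added back.
* **Sparse-cell pooling** (optional `pool_min_count`): cells whose
  *observed* count is below a threshold are merged into one Poisson class
  — a parameter-independent rule, so the objective stays consistent — and
  no logarithm ever sees a tiny, noisily estimated expectation.

The search runs Nelder–Mead in log-parameter space from the best of a set
of log-uniformly drawn starts (the surface is multimodal: besides the true
basin there are a correlated size/split-time ridge mode and a
no-migration mode), with a deliberately wide initial simplex so small-scale
MC roughness cannot collapse it. With `refine_sims`, restart winners are
re-scored on one common high-precision surface and the winner polished
there. Restart log-likelihoods computed under different random streams are
comparable only up to MC noise; the common-surface re-scoring exists
precisely to make the final comparison fair.

### Identifiability

With free daughter sizes and appreciable migration, the folded 2D-SFS
constrains the split time weakly (sizes and time trade off along a ridge);
at 8+8 haploids the profile likelihood over T is nearly flat, while at
16+16 haploids and 5×10⁴ SNPs the true basin is separated from the ridge
mode by a clear likelihood gap. The recovery experiments therefore use
16+16 haploids. Replicate estimates still fall on all three modes; the
recovery check (truth inside the middle 95% of replicate estimates)
reflects that honest scatter.

The likelihood-ratio test between nested families uses the naive 2ΔLL
against a χ² tail; no adjustment for the composite nature of the
likelihood is made (the information-matrix machinery is out of scope), so
its p-values rank models rather than calibrate error rates. Bootstrap CIs
resample SNPs with replacement from a pool greedily thinned to ≥10 kb
spacing and refit with reduced restarts seeded at the point estimate.

## Cline model

The sigmoid core is p(x) = p_min + (p_max − p_min)(1 + tanh(2(x−c)/w))/2
over elevation; exponential tails replace the sigmoid beyond c±δ, joined
continuously, with decay rate 4τ/(w(1+tanh(2δ/w))) (the hzar
parameterization). Ten variants are implemented: scaling {fixed (0,1),
free} × tails {none, left, right, mirror, both}; the default reported
model is free scaling, no tails. The likelihood is binomial with expected
frequencies clamped to [1e-9, 1−1e-9].

Sampling is single-coordinate Gaussian random-walk Metropolis–Hastings on
transformed parameters (log width and tail distances, logit bounded
fractions, center untransformed) with flat priors on the natural scale
(the transform Jacobian enters the acceptance ratio). Proposal scales
adapt per coordinate toward 20–40% acceptance during burn-in (the center's
initial scale is 10% of the elevation span) and freeze afterward. Defaults:
chain 100,000, burn-in 10,000. The MAP is the best-likelihood posterior
sample; intervals are equal-tail 2.5/97.5 posterior quantiles. AICc uses
the number of localities as the sample size and skips variants with more
parameters than localities − 2.

## Gene-set expression shifts

Genes are filtered at a mean of 10 library-size-normalized reads per
sample. TMM factors follow Robinson & Oshlack (30% M-trim, 5% A-trim,
delta-method precision weights, upper-quartile reference, geometric mean
1), with one deviation: trimming keeps values inside the M and A quantile
bounds rather than counting ranks, which makes the factors exactly
invariant to gene ordering under ties. Fold-changes are log2 ratios of
group means of effective-library-normalized counts with a prior count of
0.5 — a deliberate, documented replacement for GLM-based shrinkage
estimates; the K-S/permutation machinery downstream is preserved exactly.
The signed D statistic uses the median difference for direction; the
permutation null draws uniform random gene sets of candidate size from the
id-sorted retained genes (so results are independent of storage order),
scores each against its complement, and the decision is D > the null's
99% quantile (left-continuous ecdf).

## Synthetic data

The generators define the study conditions the tests run under:

* **Scan**: neutral SNPs from the structured coalescent; "selected" SNPs
  displace the focal-deme frequency of a neutral draw by a configured
  amount and re-sample genotypes binomially (the branch statistic responds
  to frequency displacement directly, so no selection coefficient is
  needed). Truth labels partition sites exactly.
* **Cline**: k ~ Binomial(2n, p(x)) at given elevations.
* **Expression**: log-normal gene means, negative-binomial counts with
  dispersion 0.1 by default, genotype groups defaulting to 3 LL / 8 HL /
  8 HH (the adrenal design of the motivating study), and candidate genes
  multiplied by 2^(shift·code) with codes LL=0, HL=0.5, HH=1, so `shift`
  is the injected HH-vs-LL log2 fold-change with additive heterozygotes.

What the generators deliberately do not emulate: linkage between SNPs,
sequencing/genotyping error, per-gene dispersion heterogeneity, library
composition biases beyond global scaling, and spatial autocorrelation
beyond the cline mean. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated models, not robustness to
real-data artifacts.

### The bundled sampling table

`src/altipop/data/epas1_cline_synthetic.tsv` is a *synthetic* stand-in for
the study's deposited per-locality sampling table, which is not
redistributable here. It is generated once by
`scripts/make_synthetic_reference.py` from published summary facts — 23
western-US localities, 266 mice, elevations 320–4350 m, a cline centered
at 1399.5 m, highland-allele frequency ≈0.83 at the Mt. Evans summit and
near zero on the Great Plains — with binomial sampling noise at a fixed
seed. The cline width (800 m) and scaling (0.04–0.86) are plausible
choices fixed before any test was run; because real sampling noise and
non-elevational structure differ from the binomial model, summary
statistics computed from this table (e.g. the frequency–elevation r²)
match the real table qualitatively, not digit-for-digit.

## Problem sizes

Test and acceptance runs use scaled problem sizes chosen as the package's
own balance of precision against desk-scale runtimes: 50,000 simulated
SNPs for the PBS null threshold, 50,000 replicates for simulator validity
checks, 200/20 replicates for gene-set calibration/power, 20 replicate
transects and 20 replicate SFS fits (16+16 haploids, 50,000 SNPs each) for
parameter recovery, with 100,000-step default MCMC chains shortened to
20,000–60,000 in replicate experiments. Defaults inside the package keep
the larger published values (25 optimization restarts, 100,000-step
chains, 500,000-SNP null option).
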