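# Methods

This note documents the models implemented in `founderdrift`, the
parameter choices that matter, and what the synthetic-data tests do and do
not establish about real data.

## The drift null model and the rate test

The rate test treats a quantitative trait's population mean as a random
walk driven by genetic drift. Under an additive model with narrow-sense
heritability *h²* and phenotypic variance *σ²*, one generation of drift at
size *N* perturbs the mean by a Gaussian increment with variance
*h²σ²*/*N*; over a trajectory *N₁…N_t* the standardized shift *z*/*σ* is
Gaussian with variance *h²·Σ 1/N_g* = *h²t*/*Nₑ₍ₕ₎*, where *Nₑ₍ₕ₎* is the
harmonic mean. `simulate_trait_drift` implements exactly this null;
`lande_ne_star` inverts its 95% bound:

    N*e = (1.96)² h² t / (z/σ)².

The test rejects drift when the realized *Nₑ₍ₕ₎* exceeds *N*ₑ\*. By
construction, when the test is run with the trajectory's true harmonic
mean and the matching (*h²*, *t*), the rejection rate under the null is
exactly the nominal 5% — the calibration property verified at 10⁴
replicates in the test suite and the acceptance script.

Parameter ranges and their defaults (`LandeParams`): *h²* ∈ [0.2, 0.6]
(field estimates for morphometric traits from parent–offspring, full-sib
and cross-fostering designs in a congeneric island population), generation
time ∈ [2, 3] years, elapsed time 80 years. The lower *N*ₑ\* bound pairs
the low heritability with the long generation time (*t* = 80/3 ≈ 26.667
generations, carried as a real number, never rounded); the upper bound
pairs *h²* = 0.6 with *t* = 40. These four constants force
upper/lower = 4.5 exactly, which the suite checks to machine precision.

Two standardizations are defensible for *σ*: the colonised-population SD
(the formula's definition) and the pooled two-sample SD (the scale on
which shifts are usually reported). Both are computed on every
`ShiftEstimate`; the rate test defaults to the colonised SD and accepts
`sigma="pooled"`. Shifts use natural logs of the measurements; since the
statistic is a ratio of a mean difference to an SD on the same scale, the
log base (and any multiplicative unit change) cancels.

## The founder simulator

The genetic model is a discrete Wright–Fisher chain over unlinked
biallelic loci: generation *g* draws Binomial(2·N_g, p) alleles. The
founder effect is realised as the first trajectory generation — an extreme
one-generation bottleneck at the introduction size — so the simulator is a
pure WF chain with no special founding operator. The default trajectory
(10 generations at N = 5, then recovery to N = 10⁴, 32 generations total,
*Nₑ₍ₕ₎* ≈ 16) encodes the "few founders, delayed recovery" history of a
documented human-mediated introduction: ~80 years at 2.5 years per
generation, founder size within the historically plausible 2–100 range,
recovery 19–26 generations before the present.

Mutation is off: 32 generations at the configured avian rate
(μ = 4.6×10⁻⁹/site/generation) contributes ~1.5×10⁻⁷ expected mutations
per site, negligible for every quantity tested; μ is retained in the
configuration for spectrum-scaling uses. Directional selection, when
enabled, applies the deterministic haploid-fitness update
p′ = p(1+s)/(1+ps) before each binomial draw — the simplest operator that
produces plantable sweeps (no dominance, no linkage; none is needed for
scan benchmarking).

Phenotypes are additive: trait = Σ dosage×effect over causal loci plus
Gaussian noise whose variance is solved so that Va/(Va+Ve) equals the
target *h²* in the generating (source) sample; the derived population
reuses the source-calibrated noise SD, so its realized heritability drifts
with its genetic variance, as it should. Effects are standard-normal
draws at 20 causal loci by default. When the simulated size factor is
expressed as six morphometric traits (wing, tail, tarsus, bill length/
depth/width), each measurement is baseline_mm × exp(0.05·z + ε) with
per-trait log-noise SD 0.02 — a one-factor body-size model; baselines are
realistic small-passerine values.

Source allele frequencies default to Uniform(0.05, 0.95); a Beta option
is provided because the true ascertainment distribution of reduced-
representation SNP panels is study-specific and unknown. All randomness
descends from one master seed through spawned substreams, so every
operation is bit-reproducible and partial re-runs are stable.

What the generator does **not** emulate: linkage and LD structure (loci are
independent, so the LD-pruning code is exercised only by construction),
genotyping error beyond missingness, ascertainment bias, sex/age structure,
migration, and non-additive trait architecture. Passing tests therefore
show the methods are correct under their own assumptions, not that those
assumptions hold in any particular field dataset.

## Variant filtering and LD pruning

The filter cascade fixes an order the thresholds themselves do not
determine: per-genotype masks first (GQ < 30 or DP < 8 → missing), then
site filters on the remaining calls (biallelic SNP; call rate ≥ 50%;
MAF > 0.01, with a minor-allele-count ≥ 2 alternative exposed because both
conventions are in circulation for the same step), then removal of
individuals with ≥ 30% missingness. The cascade is idempotent. LD pruning
is the greedy left-to-right scan: within 100 kb on a chromosome, the later
SNP of any pair with squared dosage correlation above the threshold is
dropped. A threshold of exactly zero is the documented intent of
"prune everything correlated", so |r| < 10⁻¹² is treated as zero to keep
floating-point noise from pruning independent sites; missing genotypes are
excluded pairwise.

## Structure and the grid bottleneck fit

Genotype PCA centers each site at 2p̂ and scales by √(2p̂(1−p̂)), mean-
imputes missing calls in scaled units, and fixes component signs by making
the largest-magnitude loading positive. The folded SFS requires complete
genotypes (sites must first be restricted to those called in everyone) so
each site is counted over the same allele number; a minor count of exactly
n/2 lands once in the top bin.

The demographic fit is deliberately a grid search, not an optimizer: each
candidate (founder size, bottleneck duration) expands to a piecewise-
constant trajectory, the WF simulator produces its expected folded
spectrum (replicates pooled before normalizing, so parameter points that
lose many loci stay comparable), and the observed spectrum is scored by
the multinomial composite log-likelihood Σᵢ obsᵢ·log(expectedᵢ) on
normalized spectra — shape only, so θ/μ never needs estimating, and the
surface is invariant to rescaling the observed counts. Default grid
resolution recovers a planted (N_intro = 5, duration 10) history within
one grid step from 5,000 sites at 20 replicates per point (~1 s); that
resolution, not the optimizer, bounds the precision. The expectation/
conditional-maximisation machinery of coalescent composite-likelihood
fitters is intentionally out of scope.

## Selection scan

The scan follows the PC-association design: MAF filter (≥ 0.1) → K = 2
genotype PCs → per-SNP regression z-scores against the score vectors →
Mahalanobis D² across SNPs (sample mean and covariance; the covariance
absorbs the scale inflation that comes from regressing SNPs on
eigenvectors of their own matrix) → genomic-inflation correction
λ = median(D²)/median(χ²_K) → BH q-values, flags at q ≤ 0.01. Under a
panmictic null the corrected p-values are uniform (KS < 0.02 at 5,000
SNPs) and essentially nothing is flagged; under a *neutral founder*
simulation the flagged fraction stays near the nominal rate on average,
with seed-to-seed variability because drift gives the D² distribution a
genuinely heavy tail.

Power to detect planted sweeps depends on the drift regime, and this is a
property of the inference problem, not of the implementation: under the
default extreme trajectory (*Nₑ₍ₕ₎* ≈ 16) two-thirds of *neutral* loci fix
in 32 generations, so a completed sweep is indistinguishable from drift
and power is ~0 for any method — the genomic mirror of the rate test's
inability to reject drift. The power benchmark therefore uses a milder
founder scenario (N = 50 for 10 generations, *Nₑ₍ₕ₎* ≈ 158) with s = 0.5
sweeps oriented toward each locus's minor source allele (sweeps on
standing variation; a sweep of an already-major allele drives the pooled
MAF below the scan's own filter). There the scan recovers ≥ 90% of 20
planted sweeps among 5,000 SNPs at q = 0.01.

Annotation proximity treats BED as 0-based half-open and GFF3 gene lines
as 1-based inclusive, converts both to 1-based inclusive internally, and
reports signed distances (negative = SNP upstream of the interval start,
0 = inside); a hit is |distance| ≤ 10 kb.

## Numerical and degenerate-input conventions

- z/σ = 0 gives *N*ₑ\* = +∞ (drift can never be rejected for a zero
  shift); decisions at exact equality never reject.
- Zero additive variance with a positive target *h²* is an error when
  calibrating noise, but tolerated when a pre-calibrated noise SD is
  supplied (a post-selection population may have lost all causal
  variation).
- Rank-sum p-values are exact by enumeration for tie-free samples with
  n ≤ 12, else normal approximation with continuity correction and
  midrank ties.
- Wright–Fisher sizes are rounded to integer allele counts (2N); absorbed
  frequencies (0 or 1) are exact and never exit.
- Problem sizes used by the test suite and acceptance script (5,000 loci
  for spectra and scans, 10⁴–10⁵ replicates for calibrations, 20 seeds for
  error-control averages) were chosen so Monte-Carlo error is well inside
  each stated tolerance; the whole suite runs in seconds.

## Known limitations

- The scan's D² null is χ² only approximately under real structure; λ
  correction aligns the median, not the tail, so strongly drifted neutral
  datasets produce some false flags (quantified above).
- The grid fit estimates two shape parameters and conditions on the rest;
  it is a demonstration-grade stand-in for full composite-likelihood
  demographic inference.
- Trait tables assume the six-column morphometric layout; covariates
  (sex, age, observer) are not modeled.
- The two printed conventions for which SD standardizes the rate test
  cannot be distinguished from the published table; both are reported and
  either can drive the decision.
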