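# Methods

## The problem

Recombination rates vary along mammalian chromosomes on the kilobase scale:
most crossing over concentrates in narrow "hotspots" embedded in a low
background. From SNP genotypes of unrelated individuals one cannot observe
crossovers directly, but the decay of linkage disequilibrium records the
population-scaled recombination rate ρ = 4·N_e·c (for autosomes), where c is
the per-generation crossover rate and N_e the effective population size.
`rhomap` infers a background-plus-hotspot map of ρ for a chromosomal region,
calls hotspot intervals by Bayes factors on 200-bp bins, and characterises
the called intervals by GC content and repeat elements — the analysis design
of fine-scale recombination surveys built on array genotypes of a few dozen
individuals (on the order of 20 diploids and 70 SNPs per ~850-kb region,
filtered to call rate ≥ 0.8 and sample MAF ≥ 0.1).

## Model

The rate map over a region of length L is piecewise constant:

    ρ(x) = β · (1 + Σ_h (λ_h − 1) · 1[x ∈ (s_h, e_h)])        x ∈ [0, L)

with background β (ρ/Mb), and hotspots h with interval (s_h, e_h) and
intensity multiplier λ_h ≥ 1 (a single hotspot elevates the local rate to
λ·β; overlapping hotspots add their excesses). Priors:

| parameter | prior | default |
|---|---|---|
| hotspot count | Poisson, rate = `hotspot_rate_per_mb` · L/Mb | 1 per Mb |
| hotspot width | Uniform(w_min, w_max) | 0.5–5 kb |
| hotspot start | Uniform over positions admitting the width | — |
| intensity λ | log-uniform(λ_min, λ_max) | 5–500 |
| background β | Exponential(mean) | mean 100 ρ/Mb |
| θ per site | log-uniform | 10⁻⁴–10⁻² |

The widths bracket the 1–2 kb hotspots of mouse and human and the up-to-5 kb
intervals reported in dog-sized SNP surveys; the intensity range covers the
10–100× elevations typical of mammalian hotspots with head-room both ways.
All bounds are constructor arguments of `PriorSpec`.

θ = 4·N_e·μ is carried in the model state (one θ per region, shared across
marker blocks) but the composite likelihood below is conditional on marker
segregation and therefore θ-free: θ's posterior equals its prior under this
engine. Pipelines that need a θ estimate should use Watterson's estimator on
the pre-ascertainment site counts; the parameter is retained so that engines
with explicit mutation modelling can drop in without an interface change.

## Likelihood: Monte-Carlo two-locus composite

Full-likelihood inference integrates over the ancestral recombination graph
and is cluster-scale. `rhomap` instead scores a candidate map by a pairwise
composite likelihood:

    ℓ(β, H) = (1/T) · Σ_{pairs (i,j): x_j − x_i ≤ span}  log P(C_ij | ρ_ij)

where C_ij is the *folded* two-locus haplotype count configuration
(n00, n01, n10, n11 up to per-locus allele relabelling) of markers i and j,
and ρ_ij = ∫ ρ(x) dx over (x_i, x_j) under the candidate map.

P(C | ρ) comes from a lookup table: for each ρ on a geometric grid
(0, 0.5, 1, 2, …, ρ_max) the two-locus ancestral process for n haplotypes is
simulated (`reps` times; ≥10⁴ recommended for production tables), one
mutation per locus is placed on a branch chosen proportionally to branch
length (the standard conditional-on-segregation, small-θ approximation), and
configuration frequencies are tabulated. Three numerical choices matter:

- **Log-probability estimation.** `log p̂ = digamma(count) − log reps`,
  which removes the leading small-count bias of `log(count/reps)`. Without
  it, grid points with diffuse configuration distributions (large ρ) are
  penalised systematically and rate estimates are biased downward.
  Configurations unseen at a grid point take a half-pseudo-count floor.
- **Ascertainment matching.** When the data's markers were filtered at a
  sample-MAF threshold, the table is built conditional on the same event
  (rejection sampling on both loci), so data and table describe the same
  sampling distribution.
- **Interpolation.** Linear in log-probability between grid nodes; pairwise
  ρ above the grid maximum is clamped to ρ_max with a logged count. The
  default grid tops at 1024; the bundled pipeline and recovery experiment
  use ρ_max = 256, which data-driven states never exceed once the pair span
  is capped, at a quarter of the simulation cost.

**Tempering.** All marker pairs share one genealogy, so the product over
pairs overstates the information in the data by roughly the number of pairs
each marker participates in. The raw composite posterior is so over-peaked
that a reversible-jump chain freezes on maps tracking individual realized
crossovers. Dividing the composite log-likelihood by a temperature T
restores usable posterior spread and mixing; the model and pipeline default
is T = 10, of the order of the mean pair redundancy under the default
100-kb span at study marker densities. T = 1 gives the raw composite.

The pair span cap (default 100 kb) limits both cost and the contribution of
distant pairs, which carry little rate information but accumulate table
noise.

Unphased genotypes are resolved to haplotypes by seeded random phasing;
missing calls are imputed with seeded draws from the marker's sample allele
frequency. Both are logged caveats: random phase attenuates observed LD and
hence biases ρ̂ upward somewhat at high heterozygosity. Simulated data carry
true haplotypes and bypass this.

## Sampler

Metropolis–Hastings with reversible-jump moves over the hotspot set: birth
(draw a hotspot from the prior; acceptance ratio Λ/(k+1) times the
likelihood ratio, with the move-weight ratio), death (uniform choice,
the exact inverse), translate, resize (log-scale, centre fixed), intensity
and background rescale (log-scale), and a θ rescale. Default move weights
0.15/0.15/0.20/0.15/0.15/0.10/0.10 and proposal scales were tuned in
preliminary runs to 20–50 % acceptance. Chains record every
`thin = iterations/4000` states and discard the first half of recordings as
burn-in, leaving ~2000 draws; `fit(n_chains=2)` runs independent chains
whose samples are pooled (the bin track is linear in the sample set).

The identical sampler with the likelihood held constant ("prior mode", no
data) yields the prior bin-occupancy q_j needed below; prior recovery of the
Poisson count (including P(≥1 hotspot) = 1 − e⁻¹ at expected count 1), the
width, intensity, background and θ distributions is property-tested.

Convergence is monitored by Geyer's initial-positive-sequence effective
sample size (autocovariance by FFT, Γ_k = ρ_{2k} + ρ_{2k+1} summed while
positive); a constant trace is reported as ESS = length with a warning.

## Hotspot designation

The region is tiled with 200-bp bins (first bin at the region start; a
partial final bin is kept and flagged). For bin j, p_j is the fraction of
posterior samples in which a hotspot interval overlaps the bin (half-open
intersection: touching an endpoint is not overlap), q_j the same under the
prior chain, and

    BF_j = [p_j/(1 − p_j)] / [q_j/(1 − q_j)]

with p and q clamped to [ε, 1−ε], ε = 1/(2M) for M samples, because prior
chains routinely produce q_j = 0. A hotspot call is a maximal run of ≥ 2
consecutive bins with BF ≥ 100; its coordinates are the outer bin edges, and
it reports bin count, mean posterior probability and mean BF. All other
bins are "neutral". The regional mean rate is the distance-weighted mean
ρ̄ = Σ ρ_i d_i / Σ d_i over inter-marker intervals (posterior-mean rates),
convertible to cM/Mb via c = ρ/(4·N_e) when an external N_e is supplied.

## Simulator

The generator is a hand-written Hudson-style back-in-time coalescent with
recombination: lineages carry ancestral-material intervals; pairs coalesce
at rate 1 (time in 2·N_e generations); a lineage recombines at rate equal to
half the rate-map integral over its ancestral span, with the breakpoint
placed by inverse CDF of the cumulative map; segments reaching their MRCA
leave the process. Infinite-sites mutations fall on recorded branch
segments at θ/2 per site, uniformly within each segment. Crossing over
only — no gene conversion, demography or selection. Validation: Watterson's
E[S], E[π] = θ, the neutral 1/i frequency spectrum, the four-gamete theorem
at ρ = 0, monotone r² decay in ρ, a local four-gamete excess across planted
hotspots, and agreement of S and π with msprime at matched scaled
parameters. The two-locus kernel used for tables is checked against an
msprime-based configuration oracle (total variation within resampling
noise).

`ascertain_markers` emulates array design: sample-MAF threshold, uniform
random thinning to a target density, and pairing of haplotypes into
diploids. `degrade_genotypes` adds independent missingness. The study
preset is 44 haplotypes, 850 kb, θ = 5·10⁻⁴/site, background 200 ρ/Mb,
~70 markers — matching the survey structure the package emulates.

What the simulator does *not* emulate: array ascertainment from an external
discovery panel (our MAF filter is within-sample), genotyping error,
population structure or bottlenecks, and gene conversion. Passing tests
therefore validate the machinery under the model's own assumptions, not
robustness to demographic misspecification.

## Recovery experiment

The end-to-end validation plants a 2-kb hotspot with λ = 30 at the centre of
a 25-kb region (background 200 ρ/Mb, θ = 3·10⁻³/site), simulates 40
haplotypes, ascertains ~60 markers (2.4/kb, MAF ≥ 0.1), runs two 20k-iteration
chains plus the prior chain, and records where the pooled posterior
occupancy track peaks. The design puts the hotspot's total scaled rate
(≈ 12) above the background total (≈ 5), the regime the method is built
for: with a genotyped region whose LD is dominated by background crossovers,
localization degrades gracefully toward the realized crossover clusters of
the sample genealogy — an information limit shared by any LD-based method,
not a sampler artifact. Across seeded replicate batches, 8–10 of 10
replicates localize the peak within ±2 kb of the true centre; the suite
asserts ≥ 8 of 10.

Problem sizes used by the test-suite and the acceptance script (tables at
4000 reps, 300 closed-form replicates, 120k prior iterations, the
2×10⁵-draw tiny-instance oracle at n=4) are desk-scale choices; production
analyses should raise table reps to ≥10⁴ and chain lengths to the point
where background ESS is a few hundred, which the summary reports.

## Annotation

GC content is (G+C)/(A+C+G+T) per bin, case-insensitive, N excluded from
the denominator (undefined for all-N bins). Repeat elements are read from
UCSC rmsk dumps or RepeatMasker `.out` files (auto-detected; `.out`
coordinates normalised to 0-based half-open). Bins are classed hotspot
(BF ≥ 100) or neutral; an element intersecting several bins of one class
counts once for that class, and class percentages are floored to whole
percent (matching per-interval element listings such as 9/22 → 40 %).
Associations: Pearson correlation of GC against log₁₀BF over all bins
jointly (per-region analysis available by subsetting), and a Welch t-test
of GC between bin classes. Degenerate inputs (constant vectors, all-N bins,
groups smaller than two) raise explicit errors rather than returning NaN.

## Known limitations

- The composite likelihood is a surrogate: its posterior spread is
  calibrated only through the temperature heuristic, so Bayes factors are
  comparable within a run but are not full-likelihood Bayes factors.
- Hotspot intensity is bounded below by the data but only weakly above:
  once local LD across a hotspot is fully broken, every larger multiplier
  fits equally well and the posterior upper tail follows the prior.
  Hotspot *positions* and the background rate are well identified;
  map-integrated mean rates over called hotspots overshoot and should be
  read as order-of-magnitude.
- Localization accuracy is bounded by marker spacing and by which
  crossovers the sample genealogy realized; sparse designs (≈12-kb marker
  spacing) mainly support regional rate estimation, not hotspot discovery.
- Random phasing and frequency-based missing-call imputation add noise for
  unphased diploid input.
- Hemizygous males on X are not modelled; X-region data should be supplied
  as diploid female genotypes or pre-phased haplotypes.
- N_e is not estimated; cM/Mb conversion requires an external N_e.
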