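# Methods

## The meiosis and cohort model

Each simulated sibling pair gets fresh parents with phased haplotypes.
Per-variant allele frequencies are drawn once per cohort from
Uniform(0.05, 0.5); parental haplotype alleles are independent
Bernoulli draws given those frequencies, i.e. the parental population
is in linkage equilibrium. There is no mutation, no sex-chromosome
handling and no population structure; these are out of scope by
design.

Four independent meioses (sperm and egg for each sib) are simulated
per pair. Crossover positions are drawn along the genetic map:

* **Poisson (default).** The break count on a map of L Morgans is
  Poisson(L); positions are uniform in cumulative-cM space and mapped
  to bp by inverse interpolation of the map. This matches the working
  assumption that each break is an independent draw from the
  recombination density.
* **Gamma renewal (optional).** Inter-crossover gaps in Morgans follow
  a gamma distribution with shape ν ≥ 1 and unit mean, giving a
  stationary renewal process with rate 1 per Morgan; the first event
  uses the length-biased (equilibrium) gap so the process has no edge
  transient. ν > 1 suppresses nearby double crossovers (positive
  interference); ν = 1 recovers Poisson exactly. Interference is a
  small effect at human crossover densities and is off by default.

A gamete transmits the chromatid labelled `a` or `b` (fair coin at the
left end) and toggles at every break; the per-variant transmitted
label is retained as the inheritance truth record. Offspring genotype
is the sum of the two gamete alleles; at a configurable rate ε each
genotype is replaced by a uniformly random *different* dosage (the
simplest symmetric error model — none is prescribed by the data the
package emulates). ε is capped at 0.05; array data is far cleaner.

**Phenotypes.** y = S + e with S the true additive score
(β_j ~ N(0, 1/M)) and e Gaussian with variance V(1−h²)/h², V being the
realized score variance — so Var(S)/Var(y) = h² by construction.
Phenotypes are assumed pre-adjusted for covariates; no covariate
machinery exists here.

**Assortative mating.** Mothers are matched to fathers by rank on a
noisy copy of the maternal score, z = S_m + sη. Comonotone matching on
z yields corr(S_f, S_m) = (1 + s²/V)^(−1/2) asymptotically; because
the analytic s undershoots slightly in finite samples, the matching
iterates (adjusting the implied correlation, at most 12 passes) until
the realized parent-score correlation is within 0.005 of the target m.
Note a single simulated generation is **not** at assortative-mating
equilibrium: offspring score variance is inflated to V₀(1 + m/2) but
the cross-locus correlations that build up over repeated generations
are absent. Consequently the covariance identity
cov(S₁,S₂) = (V/2)(1+m) recovers the injected m exactly when V is the
parental (mate-pool) variance; the `pgstats.assortativity` API
therefore takes V as an explicit argument, and real-data users should
supply the variance of an unrelated reference sample.

**Marker panel.** Markers are allocated to chromosomes proportionally
to genetic length and placed uniformly in genetic distance within each
chromosome. Placement uniform in cM keeps the probability that two
crossovers cancel inside one marker gap equal across the map; with
bp-uniform placement a narrow hotspot (e.g. 50% of the cM in 1% of the
bp) concentrates crossovers into a handful of gaps and visibly
truncates recovered map lengths at the scaled-down marker counts used
in testing. At genotyping-array density (~10⁵–10⁶ markers genome-wide)
the placement rule is immaterial.

**Default genome.** The built-in 22-autosome genome uses per-chromosome
genetic lengths summing to 3338.0 cM (the sibling-method estimates of
the autosomal map), at a uniform 1 Mbp/cM.

## Region types and truth segmentation

The 16 ordered joint inheritance patterns of a sibling pair collapse
to three region types by the number of matching parental sides: 4
identical (type 1), 8 partially identical (type 2), 4 with no IBD
(type 3). Stationary occupancy is 1/4, 1/2, 1/4. A crossover toggles
its own side's match state, so its boundary type is decided by the
*other* side's state at that position: matching → 1↔2, not matching →
2↔3, each with probability 1/2. The windowed detector sees only 1↔2
boundaries (type 2 vs type 3 similarity levels differ far less than
type 1 vs anything), hence the factor-of-two in the map estimator.
Truth segmentation reports 0-based half-open segments, boundary
brackets between flanking markers (midpoint as the point estimate —
resolution is intrinsically limited to the inter-marker gap), and the
causal parental side; simultaneous both-side toggles (apparent 1↔3
jumps, possible only through marker-gap coincidences) are flagged.

## The trio/quartet oracle

Where parental genotypes exist, sites with one parent heterozygous and
the other homozygous identify the transmitted allele of the
heterozygous parent in each child. The sib1-vs-sib2 agreement
indicator over consecutive informative sites is piecewise constant and
toggles exactly at that parent's crossover union. A running majority
vote (default window: 5 informative sites, odd windows break ties)
absorbs isolated genotyping errors; Mendelian-inconsistent sites are
skipped and counted. Boundaries closer than the smoothing window in
informative-site units cannot be resolved — the oracle's guarantee is
recovery of breaks flanked by ≥ 5 informative sites on each side.

## Detector numerics

Defaults N = 50 markers, a = 2, θ = 5, min_sep = N, chosen by the
packaged grid-search calibration (F1 on identity-boundary recovery
against truth/oracle breaks) on simulated cohorts. Missing dosages are
excluded pairwise; window counts are rescaled to the nominal N by the
co-observed fraction and positions where either window has < 0.8 N
co-observed loci are skipped. Variants with MAF < 0.05 should be
filtered before scanning (the CLI does this): stretches of
near-monomorphic markers make non-IBD regions look identical in state.
Peaks are local maxima of |Z| ≥ θ; greedy non-maximum suppression
keeps the largest |Z| within min_sep, ties to the smaller index. The
sign convention follows the indicator's algebra: Z > 0 means the right
window is the more similar one (the scan is entering an identity
region left→right).

Two undercounts are inherent and deliberately uncorrected: no calls
within N markers of chromosome ends (telomeric breaks are missed), and
type-1 segments spanning fewer than ~N markers never reach the
near-maximal window similarity that drives Z. Both losses scale
inversely with marker density: at 40 markers/cM boundary recall
plateaus near 0.93, at 100 markers/cM it exceeds 0.97, and real arrays
are denser still. Calibration excludes an edge margin (the largest N
in the grid) from both call and truth sets so these structural losses
do not distort the F1 surface.

## Map estimation

cM = 100·B/(2·n_pairs) per chromosome: four meioses per pair times 1/2
detection gives the divisor 2, yielding a sex-averaged per-meiosis
length. Standard errors treat B as Poisson — the natural model for a
count of independent events; no end-region correction is applied.
Cumulative curves are running sums of binned break midpoints rescaled
to end at the per-chromosome estimate; density histograms are raw
counts. Break positions for binning are interval midpoints (unbiased
under symmetric marker spacing).

## Risk model and health index

Absolute risk inverts the two-component equal-variance normal mixture
via Bayes' rule; computation uses log-density differences so far-tail
scores stay strictly inside (0,1). π is a required external lifetime
risk, never estimated from cohort prevalence (biobank prevalence ≠
lifetime risk). σ is taken from controls (better statistics; the model
assumes equal class SDs). Disease covariances are ignored by
construction. The index I = Σ l_d(ρ_d − r_d) is linear in the risks
and additive across diseases, but nonlinear in the scores — so sibling
index variance need not be half the population value, and two parents
who are each a high-risk outlier on a *different* disease can both
score below every midparent-clustered offspring. No published 20-disease
parameterization is shipped; configs carry illustrative values only.

## Scaled-down study sizes

Test and acceptance runs use: 500 pairs at 20,000 genome-wide markers
for genome-occupancy and break-count checks; 500 pairs on a 100 cM
chromosome at 100 markers/cM for detector recall; 1,000 pairs for
hotspot map recovery; 20,000 pairs at 500 markers for the √2-law and
parameter-recovery checks. These sizes put Monte-Carlo error
comfortably inside each check's tolerance. Marker counts are far below
real arrays; where density matters (detector recall, map-length bias)
the dependence is stated above rather than hidden.

## What passing tests do and do not show

The simulator realizes the assumptions the statistics are derived
under: additivity, linkage equilibrium, common variants, independent
crossovers, symmetric genotyping error. Passing recovery tests
therefore validates the *implementations*, not the assumptions; real
data add LD between markers, imputation artifacts structured along the
genome, low-MAF clusters, population structure and genuine crossover
interference. The MAF filter and the window rescaling address the
failure modes known to matter most (low-MAF IBD mimicry, missingness),
but no claim is made that simulated error rates bound real-data
behavior.
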