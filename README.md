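# sibkit

Sibling-pair detection of DNA recombination breaks, recombination-map
estimation, and the population-genetics statistics of sibling
polygenic-score variation — with a built-in meiosis simulator that
provides ground truth for every component.

## Who this is for

Biobanks contain tens of thousands of sibling pairs but comparatively
few parent–child trios. `sibkit` implements a method that detects
recombination events from **two sibling genotypes alone**, plus the
classical quantitative-genetics machinery used to study how sibling
polygenic scores (PGS) vary relative to the general population. Because
the interesting datasets are access-controlled, the package ships a
simulator (`sibkit.simulate`) that generates phased parents, meioses
with crossovers drawn from a genetic map, sibling genotypes with
genotyping error, and additive phenotypes under configurable
assortative mating — so every statistic can be validated by parameter
recovery before it touches real data.

## The core ideas

**IBD region types.** At any locus each sib carries one of the father's
two chromatids and one of the mother's. Of the 16 ordered joint
patterns, 4 are *identical* on both parental sides (type 1), 8 match on
exactly one side (type 2), and 4 on neither (type 3): a sibling pair is
fully identical-by-descent on about 1/4 of the genome. A crossover in
any one of the four gametes toggles one side's match state, so region
types change by one step at crossover positions.

**The break detector.** For windows of N variants flanking position
*i*, let N₊ and N₋ count loci with identical dosage in the right and
left window. The indicator

    Z = (N₊ − N₋) / (a + N − max(N₊, N₋))

spikes at boundaries between fully identical and partially identical
regions: the numerator measures the similarity discontinuity and the
denominator is small when either window is near-perfectly identical.
Local maxima of |Z| above a threshold are break calls. Type-1↔2
boundaries are half of all crossovers, so per-chromosome genetic length
is estimated from a catalog of B calls over n pairs as
cM = 100·B/(2n), with Poisson standard errors.

**Sibling PGS statistics.** For additive scores under random mating,
Var(ΔS)/Var(ΔU) = 1/2: sibling score differences have a √2-smaller
standard deviation than differences of random pairs. Spousal
resemblance enters through cov(S₁,S₂) = (V/2)(1+m), inverted to
estimate the assortativity m; the heritability captured by a score is
the average of Var(S)/Var(y) and corr(S,y)².

**Disease risk and the health index.** Case and control scores are
modeled as equal-variance normals; Bayes' rule gives the absolute risk
r(x) = [1 + ((1−π)/π)·N(x;μ₀,σ)/N(x;μ₁,σ)]⁻¹ with π the lifetime
risk. A life-year-weighted index I = Σ_d l_d(ρ_d − r_d) aggregates
across diseases; because r is nonlinear in x, the √2 law does not carry
over to I.

## Worked example

```python
import pandas as pd
from sibkit import simulate as sim, detect, recmap, pgstats

gmap = sim.GeneticMap.uniform("1", 150_000_000, 150.0)
cfg = sim.MatingConfig(n_variants=8000, error_rate=0.001, h2=0.4, seed=7)
cohort = sim.simulate_sib_pairs(1000, gmap, cfg)

calls = []
for p in range(cohort.n_pairs):
    calls += detect.call_breaks(cohort.genotypes[p, 0], cohort.genotypes[p, 1],
                                cohort.variant_pos, pair_id=f"pair{p}", chrom="1")
catalog = recmap.BreakCatalog.from_calls(calls, cohort.n_pairs)
est = recmap.estimate_map_length(catalog)
print(f"detected breaks: {len(calls)}")
print(f"estimated length: {est['cM'].iloc[0]:.1f} +- {est['SE'].iloc[0]:.1f} cM   (truth: 150.0)")

ids = cohort.sample_ids()
scores = pd.Series(cohort.true_scores.ravel(), index=ids)
sib_edges = [(ids[2*k], ids[2*k+1]) for k in range(cohort.n_pairs)]
stats = pgstats.pair_differences(
    scores, pgstats.PairSet(tuple(sib_edges)),
    pgstats.random_pairing(ids, sib_edges, seed=7), seed=7)
print(f"sqrt(2) * sd(dS)/sd(dU) = {stats.ratio:.3f} +- {stats.ratio_se:.3f}   (theory: 1)")
h2 = pgstats.heritability(cohort.true_scores.ravel(), cohort.phenotypes.ravel())
print(f"h2 (avg of variance-ratio and corr^2) = {h2.h2_avg:.3f}   (injected: 0.4)")
```

prints

```
detected breaks: 2779
estimated length: 138.9 +- 2.6 cM   (truth: 150.0)
sqrt(2) * sd(dS)/sd(dU) = 0.962 +- 0.033   (theory: 1)
h2 (avg of variance-ratio and corr^2) = 0.411   (injected: 0.4)
```

The ~7% shortfall of the detector-based length estimate is the
method's documented undercount: no calls are made within N variants of
chromosome ends, and identity segments spanning fewer than N markers
are invisible to the windowed scan. Both losses shrink with marker
density (this example uses 53 markers/cM; genotyping arrays provide
~200/cM). Estimates built from truth boundaries — or from denser panels
— recover simulated map lengths within Poisson error (see
`tests/test_acceptance.py`).

## Command line

Each library stage has a thin CLI wrapper:

```sh
sibkit simulate --map map.tsv --pairs 500 --h2 0.4 --seed 1 --out cohort/
sibkit detect   --geno cohort/genotypes.tsv --pairs cohort/pairs.tsv --out breaks.bed
sibkit recmap   --breaks breaks.bed --pairs-count 500 --bin-kb 500 --out maps/
sibkit pgstats  --geno cohort/genotypes.tsv --weights cohort/weights.tsv \
                --pheno pheno.tsv --pairs cohort/pairs.tsv --out stats/
sibkit riskindex --config index.yaml --scores scores.tsv --out risks.tsv
sibkit calibrate --geno ... --pairs ... --truth oracle.bed --out calib/
```

Formats: dosage TSV (`variant_id  chrom  pos  sample…`, "." missing) or
VCF for genotypes; 4-column HapMap-style genetic maps; BED-like break
catalogs (0-based half-open intervals).

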