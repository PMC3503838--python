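# gmyc — Bayesian and ML species delimitation with the GMYC model

Single-locus DNA-sequence surveys (barcoding, environmental sampling) often
need putative species boundaries where no usable taxonomy exists.  The
general mixed Yule-coalescent (GMYC) model delimits species from an
ultrametric gene tree by assuming that branching events older than a
threshold time are speciations (a Yule process) while younger events are
within-species coalescences, and locating the threshold statistically.

This package implements:

* the GMYC likelihood and a **maximum-likelihood threshold scan** with
  likelihood-ratio test and per-threshold Akaike weights;
* a **Bayesian MCMC** over the threshold rank and the two rate-change
  exponents, with uniform priors and profiled branching rates; running one
  chain per tree over a sample from a clock-model tree posterior and pooling
  the draws marginalizes species limits over phylogenetic uncertainty;
* the **simulation framework** used to validate the method: Yule species
  trees subsampled and scaled to fixed depths (in N-generation units),
  multispecies-coalescent gene trees with fixed or lognormal allele
  sampling, strict-clock HKY+G sequence simulation, and a finite
  island-model structured coalescent;
* posterior **summaries**: species-number PMF/mean/95% HPD, pairwise
  co-conspecificity matrices, consensus partitions, Akaike-weight vs
  posterior comparisons.

## Model

For a rooted ultrametric tree with `n` tips there are `m = n - 1` branching
events; the data are the `m - 1` waiting times `x_i` between successive
events.  Given a threshold rank `T` (the `T - 1` oldest events are
speciations, so `T` lineages cross the threshold), each waiting interval
carries a combined hazard

```
b_i = λ_y · n_{i,y}^{p_y}  +  λ_c · Σ_j ( n_{i,j} (n_{i,j} − 1) )^{p_c}
```

where `n_{i,y}` counts interspecific lineages, `n_{i,j}` the within-species
lineages of cluster `j`, `λ_y, λ_c` are the branching rates (one shared pair
across all coalescent processes; `λ_c ≈ 1/(N_e μ)`), and `p_y, p_c` are
rate-change exponents.  Each waiting time is exponential, `L(x_i) = b_i
e^{-b_i x_i}`.  Rates are profiled at their conditional maxima (the combined
log likelihood is concave in the rates); the threshold and exponents are
optimized (ML) or sampled (MCMC, priors `T ~ U{2..n}`, `p ~ U(0,2)`).
The single-process coalescent null model yields an LR test for the presence
of a threshold.

## Worked example

Simulate a gene tree for 10 species (5 alleles each) under the multispecies
coalescent in a Yule species tree of depth 80 N generations, then delimit:

```python
import numpy as np
from gmyc import ml_scan, run_chain, ChainConfig, species_number_summary
from gmyc.simulate import simulate_yule_species_tree, simulate_msc_gene_tree

species = simulate_yule_species_tree(30, 10, depth=80.0, seed=7)
gene = simulate_msc_gene_tree(species, np.full(10, 5), seed=8)

res = ml_scan(gene)
print(res.report())

trace = run_chain(gene, config=ChainConfig(n_steps=20000, burnin=2000,
                                           thin=10, seed=1))
s = species_number_summary(trace)
print(f"posterior mean {s.mean:.2f}, 95% HPD [{s.hpd_lower}, {s.hpd_upper}]")
```

Output:

```
GMYC maximum-likelihood threshold scan
  thresholds evaluated : 49
  best threshold rank  : T = 7  (7 entities)
  log L (best / null)  : 41.3100 / 30.2602
  LR = 22.0996, df = 3, p = 6.219e-05
  7 species with a support interval (2 logL units) of 7 to 11
  top Akaike weights   : T=7: 0.295, T=10: 0.291, T=9: 0.159, T=11: 0.110, T=8: 0.091
posterior mean 9.61, 95% HPD [7, 12]
```

The threshold model is decisively preferred over the one-population null
(LR = 22.1, p < 1e-4).  The ML point estimate is 7 entities, but the
support interval (7-11) and the Akaike weights show a second, nearly
equally weighted peak at the true 10; the Bayesian posterior — which
averages over this uncertainty instead of committing to a point — centers
on 9.6 species with a 95% HPD of [7, 12].  On a single locus with 10
species, this flat ridge between merging and splitting a couple of shallow
clades is typical, and is exactly why the posterior summaries are the
recommended interface.  `gmyc --help` exposes the same workflow from the shell
(`fit-ml`, `fit-bayes`, `simulate`, `summarize`, `dedupe`), including
NEXUS `.trees` ingestion with burn-in/thinning for posterior tree samples
and exact-duplicate sequence removal before clock-tree estimation.

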