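# Methods

## The model

An ultrametric gene tree for `n` sequences has `m = n - 1` branching events
at ages `t_1 > t_2 > ... > t_m` (tips at age 0).  The data are the `m - 1`
inter-event waiting times `x_i = t_i - t_{i+1}`; the pre-root stem and the
segment from the youngest event to the present carry no event and are
excluded (no censoring term).

A threshold rank `T ∈ {2..n}` classifies the `T - 1` oldest events as
speciations and the rest as within-species coalescences; exactly `T`
lineages cross the threshold, each subtending one delimited entity.  An
entity with ≥ 2 tips (a *cluster*) carries a coalescent process; singletons
and the not-yet-branched stems of clusters are carried by the interspecific
(Yule) process, so in every interval the Yule count plus the within-cluster
counts equals the number of lineages.

Interval `i` (with `i + 1` lineages) has combined hazard

    b_i = λ_y · A_i^{p_y} + λ_c · Σ_j ( n_{ij}(n_{ij} − 1) )^{p_c},

and the likelihood is `Π_i b_i exp(-b_i x_i)` — the marginal density of the
waiting times.  `λ_c` is interpretable as `1/(N_e μ)` in the tree's time
units, `p = 1` is the neutral no-rate-change case for both exponents, and
one `(λ_c, p_c)` pair is shared by all coalescent processes.

### Rate profiling

For fixed exponents the combined log likelihood is concave in `(λ_y, λ_c)`
(a sum of logs of linear functions minus a linear function), so the rate
MLEs are computed exactly by a damped 2-D Newton iteration with positivity
backtracking (gradient tolerance 1e-11·m, L-BFGS-B fallback in log-space on
the rare non-convergence).  The MCMC and the ML scan profile the rates at
every evaluation; warm starts make a profiled evaluation essentially one or
two Newton steps.

### The event-attribution form

A second likelihood form is provided (`mode="attribution"` and
`profile_lambdas`): each event contributes the hazard of *its own* process
while survival uses the combined `b`.  Only events whose own waiting
segment is one of the observed intervals carry a rate factor — Yule events
of rank 2..T−1 (the root has no preceding interval) and coalescent events
of rank T..m−1 (the youngest event's backward segment runs into the
excluded tip-to-present segment).  This form factorizes per process, gives
the closed-form rate MLEs

    λ̂ = (#events of the process) / Σ_i c_i x_i,

and reduces exactly to the combined form whenever a single process is
active (the null model, or `T = n`).  It is, however, the joint density of
(waiting time, which process fired): its event-type data change with the
threshold, each coalescent event pays ~log(#active processes) relative to
the marginal form, and a threshold scan under it collapses to `T = n`.  It
is therefore offered as a rate estimator and for sensitivity analysis, not
as the scan/posterior objective.

### ML scan, null model, uncertainty

`ml_scan` maximizes the profiled likelihood over `(p_y, p_c)` in a box
(default `[0, 2]`, Nelder–Mead started at the neutral `p = 1`) for every
`T`, reports the smallest `T` attaining the maximum, a likelihood-ratio
test against the single-coalescent-process null (df = 3 by default:
threshold + extra rate + extra exponent; configurable), per-threshold
Akaike weights `w_T ∝ exp(−Δ_T/2)` (all threshold models share a parameter
count), and a 2-logL support interval.

### MCMC

Metropolis–Hastings over `(T, p_y, p_c)` with flat priors (`T ~ U{2..n}`
inclusive, `p ~ U(0, 2)`), rates profiled at every step.  Each step updates
one coordinate chosen uniformly: `T` by a symmetric integer walk (step
uniform in `{−3..3}\{0}`, folded about the half-integer barriers — folding
about the boundary *values* would double-count moves into the edge states
and bias the kernel, which the prior-recovery test catches); `p`'s by
sliding windows of width 0.2 reflected at the prior bounds.  Chains start
from the argmax of a coarse (≤ 32-point) profiled-likelihood scan: a ±3
walk cannot traverse the nearly flat likelihood tail of a large tree within
a short burn-in, and uniform-random starts were observed to maroon chains
hundreds of ranks from the mode.  Prior-only validation runs keep the
random start.

Protocol defaults mirror the validation study: simulations 100k steps / 10k
burn-in / thin 100; empirical-style tree-sample runs 10k / 1k / 100 (100
trees × 90 retained samples = 9,000 pooled draws).  Multi-tree runs derive
per-tree seeds from one top-level seed, fail if tip sets differ, and tag
every retained sample with its tree id.  Convergence is reported via
autocorrelation ESS (arviz) with a warning threshold of 150; acceptance
rates are logged per move type.

### Summaries

The species-number posterior is summarized by its mean, mode, PMF and a
discrete 95% HPD — the smallest *contiguous* integer interval with ≥ 95%
mass (threshold rank is ordinal; ties break toward the narrower interval,
then smaller values).  Pairwise co-conspecificity uses each retained
sample's own tree: tips are conspecific iff their MRCA age is strictly
below the sample's threshold time (the age of the `T−1`-th ranked event).
Consensus partitions single-link pairs above a probability cutoff in
(0.5, 1] and report non-transitive pairs; they are a lossy export
convenience relative to the marginal matrix.

## Synthetic data

All simulators work in **N-generation units**: `N` diploid individuals per
species (or per deme), per-pair coalescence rate 1/2 per N generations
(mean pairwise TMRCA 2 N), doubled under the haploid/organellar convention
(equivalent depths halve; `N` becomes the effective number of females).
Time to substitutions per site uses `μ = θ/(4N)` per generation, i.e.
`depth = t_N · θ/4`.

* **Yule species trees** — constant-rate pure birth grown forward to
  `n_grow` tips (observed just before the next birth), `n_sample` tips
  retained uniformly at random, induced tree rescaled so the sample MRCA
  sits at a fixed depth.  The growth rate is immaterial under rescaling.
  Study conditions: 150 grown, 50 retained, depths 20/40/80/160 N.
* **MSC gene trees** — Kingman coalescent within each species branch,
  survivors entering the ancestral population at each speciation time.
  Allele sampling: fixed k ∈ {2, 5, 10} or `ceil(Lognormal(meanlog=1,
  sdlog=1))` (mean ≈ e^1.5 + 0.5 ≈ 4.98 alleles, ≈ Φ(−1) ≈ 15.9%
  singletons; the ceiling is the discretization consistent with both of
  those operating figures, and guarantees ≥ 1 allele).
* **Sequences** — strict-clock HKY+G by matrix exponentiation; defaults
  κ = 4, gamma shape 0.5 with 4 median-rate categories normalized to mean
  1, equal base frequencies, θ = 0.015 (all configurable; only θ, the model
  family and the lengths are pinned by the study design).
* **Island model** — D demes of size N; within-deme pair coalescence at
  rate 1/2, per-lineage migration at rate `Nm` to a uniform other deme.
  Reports the TMRCA and the scattering-phase end (first time every lineage
  occupies a distinct deme).  Default sampling 5 lineages from each of 10
  demes; the TMRCA is collecting-phase dominated and insensitive to this
  choice (halving or doubling the per-deme sample moves the mean TMRCA by
  far less than its replicate spread).

The MSC and island simulators are cross-validated against msprime
(two-sample KS on TMRCA distributions) in the test suite; the Yule
generator's branch-length statistics were cross-checked against R/ape.

What the generator does **not** emulate: mutational noise in the tree used
for inference (the depth/sampling experiments fit the *true* gene tree, so
they isolate model error from phylogenetic error), recombination,
selection, migration between the delimited species, and clock-model
misspecification.  Passing tests therefore demonstrate correctness of the
inference machinery and its behavior across demographic regimes, not
robustness to tree-estimation error — for that, feed a posterior `.trees`
sample from external clock software to `fit-bayes`.

## Experiment drivers and scale

`run_experiment` chains simulate → fit → summarize and never drops a
failed replicate silently (a `status` column records failures).  Default
desk-scale protocols: the depth experiment (50 species × 5 alleles at
20/40/80/160 N) uses 30 replicate trees per depth with 30k-step chains in
the acceptance script and 10 × 20k in the test suite; the sampling
experiment (depth 80 N, schemes 2/5/10/lognormal) 10 × 20k.  The full-scale
protocol of record is 50 replicates with 100k-step chains.

## Numerical choices and degenerate inputs

* Ultrametricity: root-to-tip depths must agree within relative 1e-6; ages
  are renormalized to `mean tip depth − node depth`, tips pinned to 0.
* Tied node ages (duplicate sequences, polytomies — the latter resolved to
  zero-length branches) are rejected with advice to deduplicate
  (`gmyc dedupe`); an opt-in jitter perturbs ties by ≤ 1e-8 × root age,
  preserving parent-child order.
* A process with no events at a threshold is dropped from the profiled
  likelihood (rate reported as `nan`); an interval with zero combined
  hazard yields −inf with a warning.
* Thresholds where the optimizer fails are excluded from the ML scan with a
  warning, never silently.
* Exponent optimization starts at the neutral `p = 1`; `p_c` is weakly
  identified when all clusters hold the same lineage count (e.g. uniformly
  2 alleles), which is harmless: the profiled rate absorbs the scale.

## Known limitations

* Single threshold only; no multiple-threshold or reversible-jump variant.
* Single locus; discordance between gene tree and species history is
  inherited, not modeled.
* The likelihood conditions on the tree: joint tree + delimitation
  inference is out of scope (tree uncertainty enters only through pooling
  over an externally supplied tree sample).
* Species whose divergence is younger than the within-species coalescent
  time scale (≲ 4 N generations) are not identifiable under the model; in
  that regime credible intervals are known to become unreliable rather
  than gracefully wide.
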