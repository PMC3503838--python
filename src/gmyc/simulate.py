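"""Synthetic-data generators defining the validation study conditions.

Yule species trees (grown to 150 tips, 50 retained at random) scaled to
fixed depths in N-generation units; multispecies-coalescent gene trees with
fixed or lognormal allele sampling; HKY+G sequence simulation; a finite
island-model structured coalescent; and end-to-end experiment drivers.

Units
-----
All genealogies are in **N-generation** units, where N is the (diploid)
effective population size of one species (or one deme for the island model).
A diploid pair then coalesces at rate 1/2 per N generations (mean pairwise
TMRCA 2 N); the haploid/organellar convention doubles the rate, halving all
coalescent times.  Time-to-substitutions conversion uses mu = theta/(4N) per
generation, i.e. ``substitutions = t_N * theta / 4``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .bayes import ChainConfig, PriorSpec, run_chain
from .trees import UltrametricTree

__all__ = [
    "SamplingScheme",
    "IslandModelConfig",
    "SeqSimConfig",
    "IslandGenealogy",
    "simulate_yule_species_tree",
    "simulate_msc_gene_tree",
    "draw_sampling",
    "simulate_sequences",
    "simulate_island_genealogy",
    "tmrca_to_substitutions",
    "run_experiment",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def pair_rate(ploidy: str) -> float:
    """Per-pair coalescence rate in N-generation units."""
    if ploidy == "diploid":
        return 0.5
    if ploidy == "haploid":
        return 1.0
    raise ValueError("ploidy must be 'diploid' or 'haploid'")


# ---------------------------------------------------------------------------
# tree assembly helper
# ---------------------------------------------------------------------------


def _build_tree(
    tip_labels: list[str],
    merges: list[tuple[int, int, float]],
    units: str = "N_generations",
) -> UltrametricTree:
    """Assemble an UltrametricTree from tips and (left, right, age) merges.

    Merge operands index tips (0..n-1) or earlier merges (n, n+1, ...).
    """
    n = len(tip_labels)
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int64)
    age = np.zeros(total)
    for k, (a, b, t) in enumerate(merges):
        v = n + k
        parent[a] = v
        parent[b] = v
        age[v] = t
    return UltrametricTree(parent, age, tip_labels, units=units, min_tips=2)


# ---------------------------------------------------------------------------
# Yule species trees
# ---------------------------------------------------------------------------


def simulate_yule_species_tree(
    n_grow: int = 150,
    n_sample: int = 50,
    depth: float = 80.0,
    seed=None,
) -> UltrametricTree:
    """Pure-birth species tree, subsampled and rescaled to a fixed depth.

    A constant-rate Yule tree is grown forward until ``n_grow`` extant
    lineages exist (observed just before the next birth), ``n_sample`` tips
    are retained uniformly at random, and the induced tree is rescaled so
    the root (MRCA of the sample) sits at age ``depth``.  The growth rate is
    immaterial because of the rescaling.
    """
    if n_sample < 2:
        raise ValueError("n_sample must be >= 2")
    if n_sample > n_grow:
        raise ValueError("n_sample cannot exceed n_grow")
    rng = _rng(seed)
    # forward growth: record split times and which active lineage split
    t = 0.0
    split_times: list[float] = []
    splitters: list[int] = []
    k = 1
    while k < n_grow:
        t += rng.exponential(1.0 / k)
        split_times.append(t)
        splitters.append(int(rng.integers(k)))
        k += 1
    t_end = t + rng.exponential(1.0 / n_grow)

    # replay: each active lineage carries the id of its parent node
    # (-1 for the pre-root stem); a split materializes an internal node
    n = n_grow
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    age = np.zeros(2 * n - 1)
    active_parent: list[int] = [-1]
    for j, (ts, who) in enumerate(zip(split_times, splitters)):
        v = n + j
        age[v] = t_end - ts
        parent[v] = active_parent[who]
        active_parent[who] = v
        active_parent.append(v)
    for i, p in enumerate(active_parent):
        parent[i] = p
    labels = [f"s{i + 1}" for i in range(n)]
    tree = UltrametricTree(parent, age, labels, units="N_generations",
                           min_tips=2)
    if n_sample < n_grow:
        keep = sorted(rng.choice(n, size=n_sample, replace=False).tolist())
        tree = _induced_subtree(tree, keep)
    # rescale so the sampled MRCA sits at `depth`
    scale = depth / tree.root_age
    age2 = tree.age * scale
    return UltrametricTree(tree.parent, age2, tree.labels,
                           units="N_generations", min_tips=2)


def _induced_subtree(tree: UltrametricTree, keep_tips: list[int]) -> UltrametricTree:
    """Subtree induced by a tip subset, rooted at their MRCA; ages preserved."""
    n = tree.n_tips
    kids = tree.children()
    keep = set(keep_tips)
    # iterative post-order: representative node in the induced tree per node
    rep: dict[int, int | None] = {}
    merges: list[tuple[int, int, float]] = []
    new_tip_ids = {tip: i for i, tip in enumerate(sorted(keep))}
    labels = [tree.labels[tip] for tip in sorted(keep)]
    order: list[int] = []
    stack = [tree.root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(kids[v])
    n_new = len(keep)
    for v in reversed(order):
        if v < n:
            rep[v] = new_tip_ids[v] if v in keep else None
            continue
        sub = [rep[c] for c in kids[v] if rep[c] is not None]
        if len(sub) == 0:
            rep[v] = None
        elif len(sub) == 1:
            rep[v] = sub[0]
        else:
            merges.append((sub[0], sub[1], float(tree.age[v])))
            rep[v] = n_new + len(merges) - 1
    return _build_tree(labels, merges, units=tree.units)


# ---------------------------------------------------------------------------
# sampling schemes
# ---------------------------------------------------------------------------


@dataclass
class SamplingScheme:
    """Alleles sampled per species: fixed count or discretized lognormal.

    The lognormal scheme draws X ~ Lognormal(meanlog, sdlog) and takes the
    ceiling, guaranteeing >= 1 allele per species.  With the default
    meanlog = sdlog = 1 this gives a mean of ~5 alleles per species and
    ~16% singleton species.
    """

    kind: str = "fixed_k"
    k: int = 5
    meanlog: float = 1.0
    sdlog: float = 1.0

    def __post_init__(self):
        if self.kind not in ("fixed_k", "lognormal"):
            raise ValueError("kind must be 'fixed_k' or 'lognormal'")
        if self.kind == "fixed_k" and self.k < 1:
            raise ValueError("k must be >= 1")


def draw_sampling(scheme: SamplingScheme, n_species: int, seed=None) -> np.ndarray:
    """Vector of allele counts per species under a sampling scheme."""
    rng = _rng(seed)
    if scheme.kind == "fixed_k":
        return np.full(n_species, scheme.k, dtype=np.int64)
    draws = rng.lognormal(scheme.meanlog, scheme.sdlog, size=n_species)
    return np.ceil(draws).astype(np.int64)


# ---------------------------------------------------------------------------
# multispecies coalescent
# ---------------------------------------------------------------------------


def simulate_msc_gene_tree(
    species_tree: UltrametricTree,
    scheme: SamplingScheme | np.ndarray | list | None = None,
    N: float = 1.0,
    ploidy: str = "diploid",
    seed=None,
) -> UltrametricTree:
    """Coalescent gene tree embedded in a species tree.

    Within every species-tree branch the sampled lineages follow a Kingman
    coalescent with constant population size ``N`` (the unit of the species
    tree's branch lengths: times are in N-generation units, so the per-pair
    rate is 1/2 for diploids, 1 for haploids); surviving lineages enter the
    ancestral population at each speciation time, and coalescence completes
    above the root.  Alleles are labeled ``<species>_<i>``.
    """
    rng = _rng(seed)
    rate = pair_rate(ploidy) / N
    scheme = SamplingScheme() if scheme is None else scheme
    if isinstance(scheme, SamplingScheme):
        counts = draw_sampling(scheme, species_tree.n_tips, rng)
    else:
        counts = np.asarray(scheme, dtype=np.int64)
        if counts.shape[0] != species_tree.n_tips:
            raise ValueError("allele-count vector length != number of species")
        if np.any(counts < 1):
            raise ValueError("every species needs >= 1 allele")

    labels: list[str] = []
    tip_sets: list[list[int]] = []
    for j, sp in enumerate(species_tree.labels):
        ids = []
        for i in range(counts[j]):
            ids.append(len(labels))
            labels.append(f"{sp}_{i + 1}")
        tip_sets.append(ids)
    n_gene = len(labels)

    merges: list[tuple[int, int, float]] = []

    def coalesce(lineages: list[int], t0: float, t1: float) -> list[int]:
        lineages = list(lineages)
        t = t0
        while len(lineages) > 1:
            k = len(lineages)
            t += rng.exponential(1.0 / (k * (k - 1) / 2 * rate))
            if t > t1:
                break
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            merges.append((a, b, t))
            node = n_gene + len(merges) - 1
            lineages = [x for x in lineages if x not in (a, b)] + [node]
        return lineages

    # process species-tree nodes young -> old
    kids = species_tree.children()
    pending: dict[int, list[int]] = {}
    for j, sp in enumerate(species_tree.labels):
        p = species_tree.parent[j]
        top = species_tree.age[p] if p >= 0 else np.inf
        pending[j] = coalesce(tip_sets[j], 0.0, top)
    internal = [
        v
        for v in range(species_tree.n_tips, 2 * species_tree.n_tips - 1)
    ]
    internal.sort(key=lambda v: species_tree.age[v])
    for v in internal:
        incoming: list[int] = []
        for c in kids[v]:
            incoming.extend(pending.pop(c))
        p = species_tree.parent[v]
        top = species_tree.age[p] if p >= 0 else np.inf
        pending[v] = coalesce(incoming, float(species_tree.age[v]), float(top))
    (last,) = pending.values()
    assert len(last) == 1
    return _build_tree(labels, merges, units="N_generations")


# ---------------------------------------------------------------------------
# sequence simulation (HKY + discrete gamma)
# ---------------------------------------------------------------------------


@dataclass
class SeqSimConfig:
    """Strict-clock HKY+G sequence simulation settings.

    ``theta = 4 N mu`` per site links the gene tree's N-generation branch
    lengths to substitutions per site (``brlen_subs = brlen_N * theta / 4``).
    """

    length: int = 600
    theta: float = 0.015
    kappa: float = 4.0
    gamma_shape: float = 0.5
    n_categories: int = 4
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.length <= 0 or self.theta <= 0:
            raise ValueError("length and theta must be positive")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")


_BASES = np.array(list("ACGT"))


def _hky_Q(kappa: float, freqs) -> np.ndarray:
    """HKY85 rate matrix scaled to one expected substitution per unit time."""
    pi = np.asarray(freqs, dtype=float)
    Q = np.zeros((4, 4))
    # order A, C, G, T; transitions: A<->G (0,2), C<->T (1,3)
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            ti = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
            Q[i, j] = (kappa if ti else 1.0) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    return Q / scale


def _gamma_category_rates(shape: float, k: int) -> np.ndarray:
    """Median discrete-gamma category rates, normalized to mean 1."""
    qs = (2 * np.arange(k) + 1) / (2 * k)
    rates = stats.gamma.ppf(qs, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


def simulate_sequences(
    gene_tree: UltrametricTree,
    config: SeqSimConfig | None = None,
    seed=None,
) -> dict[str, str]:
    """Simulate an alignment on a gene tree under a strict clock.

    Returns ``{tip label: sequence}``; per-site rate categories are shared
    across the tree (classic discrete-gamma site rates).
    """
    cfg = config or SeqSimConfig()
    rng = _rng(seed)
    Q = _hky_Q(cfg.kappa, cfg.base_freqs)
    cat_rates = _gamma_category_rates(cfg.gamma_shape, cfg.n_categories)
    L = cfg.length
    site_cat = rng.integers(cfg.n_categories, size=L)
    freqs = np.asarray(cfg.base_freqs)

    kids = gene_tree.children()
    states = {gene_tree.root: rng.choice(4, size=L, p=freqs)}
    out: dict[str, str] = {}
    stack = [gene_tree.root]
    while stack:
        v = stack.pop()
        sv = states.pop(v)
        if v < gene_tree.n_tips:
            out[gene_tree.labels[v]] = "".join(_BASES[sv])
            continue
        for c in kids[v]:
            brlen_subs = (
                float(gene_tree.age[v] - gene_tree.age[c]) * cfg.theta / 4.0
            )
            sc = sv.copy()
            for cat in range(cfg.n_categories):
                mask = site_cat == cat
                if not mask.any():
                    continue
                P = linalg.expm(Q * brlen_subs * cat_rates[cat])
                P = np.clip(P, 0, None)
                P /= P.sum(axis=1, keepdims=True)
                probs = P[sv[mask]]
                u = rng.random(mask.sum())
                sc[mask] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
            states[c] = sc
            stack.append(c)
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# island-model structured coalescent
# ---------------------------------------------------------------------------


@dataclass
class IslandModelConfig:
    """Finite island model: D demes of size N, Nm migrants/deme/generation.

    ``lineages_per_deme`` lineages are sampled from each of
    ``demes_sampled`` demes.  Times are in N-generation units with N one
    deme's size, so the per-lineage migration rate is ``Nm`` and the
    within-deme pair-coalescence rate is 1/2 (diploid) or 1 (haploid).
    """

    n_demes: int = 200
    Nm: float = 0.07
    demes_sampled: int = 10
    lineages_per_deme: int = 5
    ploidy: str = "diploid"

    def __post_init__(self):
        if not 0 < self.demes_sampled <= self.n_demes:
            raise ValueError("require 0 < demes_sampled <= n_demes")
        if self.Nm <= 0 and self.n_demes > 1:
            raise ValueError("Nm must be > 0")
        pair_rate(self.ploidy)


@dataclass
class IslandGenealogy:
    """A structured-coalescent genealogy plus its headline summaries."""

    tree: UltrametricTree
    tmrca: float
    scattering_end: float
    n_lineages_after_scattering: int


def simulate_island_genealogy(
    config: IslandModelConfig | None = None, seed=None
) -> IslandGenealogy:
    """Structured coalescent under the finite island model.

    Lineages coalesce pairwise within demes and migrate to a uniformly
    chosen other deme at rate ``Nm`` per lineage.  The scattering phase ends
    the first time every surviving lineage occupies a distinct deme; the
    slow collecting phase then dominates the TMRCA.
    """
    cfg = config or IslandModelConfig()
    rng = _rng(seed)
    rate = pair_rate(cfg.ploidy)
    D = cfg.n_demes
    mig = cfg.Nm if D > 1 else 0.0

    deme_of: list[int] = []
    labels: list[str] = []
    for d in range(cfg.demes_sampled):
        for i in range(cfg.lineages_per_deme):
            labels.append(f"d{d + 1}_{i + 1}")
            deme_of.append(d)
    n = len(labels)
    lineage_ids = list(range(n))
    occ = np.zeros(D, dtype=np.int64)
    for d in deme_of:
        occ[d] += 1

    merges: list[tuple[int, int, float]] = []
    t = 0.0
    scattering_end = 0.0 if occ.max() <= 1 else None
    n_after_scatter = n if scattering_end == 0.0 else None
    S2 = float(np.sum(occ * (occ - 1) / 2))
    while len(lineage_ids) > 1:
        k = len(lineage_ids)
        total = S2 * rate + k * mig
        t += rng.exponential(1.0 / total)
        if rng.random() < (S2 * rate) / total:
            # coalescence in a deme chosen proportionally to its pair count
            pairs = occ * (occ - 1) / 2
            d = int(rng.choice(D, p=pairs / pairs.sum()))
            members = [i for i, li in enumerate(lineage_ids) if deme_of[li] == d]
            ii, jj = rng.choice(len(members), size=2, replace=False)
            a = lineage_ids[members[ii]]
            b = lineage_ids[members[jj]]
            merges.append((a, b, t))
            node = n + len(merges) - 1
            while len(deme_of) <= node:
                deme_of.append(-1)
            deme_of[node] = d
            lineage_ids = [x for x in lineage_ids if x not in (a, b)] + [node]
            occ[d] -= 1
            S2 -= occ[d]
        else:
            li = lineage_ids[int(rng.integers(k))]
            d_old = deme_of[li]
            d_new = int(rng.integers(D - 1))
            if d_new >= d_old:
                d_new += 1
            deme_of[li] = d_new
            occ[d_old] -= 1
            S2 -= occ[d_old]
            occ[d_new] += 1
            S2 += occ[d_new] - 1
        if scattering_end is None and occ.max() <= 1:
            scattering_end = t
            n_after_scatter = len(lineage_ids)
    tree = _build_tree(labels, merges, units="N_generations")
    return IslandGenealogy(
        tree=tree,
        tmrca=t,
        scattering_end=float(scattering_end if scattering_end is not None else t),
        n_lineages_after_scattering=int(
            n_after_scatter if n_after_scatter is not None else 1
        ),
    )


def tmrca_to_substitutions(
    tmrca: float, theta_per_deme: float, denominator_demes: int = 1
) -> float:
    """Convert a TMRCA in N-generation units to substitutions per site.

    With ``theta = 4 N mu`` per deme, ``mu = theta / (4N)`` per generation
    and depth = ``tmrca * theta / 4``.  ``denominator_demes`` divides theta
    for the reading where a total theta is split across demes.
    """
    if theta_per_deme <= 0:
        raise ValueError("theta must be > 0")
    return tmrca * (theta_per_deme / denominator_demes) / 4.0


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

DEPTH_GRID = (20.0, 40.0, 80.0, 160.0)
SCHEME_GRID = ("2", "5", "10", "lognormal")
SEQLEN_GRID = (300, 600, 1200, 2400)


def _fit_one(
    gene_tree: UltrametricTree,
    chain: ChainConfig,
    seed: int,
) -> dict:
    """Bayesian fit of one simulated gene tree; headline posterior summaries."""
    from .summarize import species_number_summary

    cfg = ChainConfig(
        n_steps=chain.n_steps,
        burnin=chain.burnin,
        thin=chain.thin,
        t_step=chain.t_step,
        p_window=chain.p_window,
        seed=seed,
    )
    trace = run_chain(gene_tree, PriorSpec(), cfg)
    summ = species_number_summary(trace)
    frac_young = float((trace.samples["threshold_time"] < 4.0).mean())
    return dict(
        posterior_mean=summ.mean,
        hpd_lower=summ.hpd_lower,
        hpd_upper=summ.hpd_upper,
        frac_steps_below_4N=frac_young,
        n_samples=len(trace.samples),
    )


def run_experiment(
    experiment: str,
    replicates: int = 10,
    seed: int = 0,
    depths=DEPTH_GRID,
    schemes=SCHEME_GRID,
    seq_lengths=SEQLEN_GRID,
    n_species_grow: int = 150,
    n_species: int = 50,
    alleles_per_species: int = 5,
    chain: ChainConfig | None = None,
) -> pd.DataFrame:
    """End-to-end simulate -> fit -> summarize driver.

    ``experiment`` is one of:

    - ``"depth"``: species trees scaled to each depth in ``depths`` (N
      generations), 5 alleles/species, Bayesian GMYC on the true gene tree.
    - ``"sampling"``: depth 80 N, sampling schemes 2/5/10/lognormal.
    - ``"seqlen"``: depth 160 N, HKY+G alignments of each length simulated
      on the true gene tree (reported with unique-sequence counts) and the
      Bayesian fit of the true tree as reference; clock-tree re-estimation
      is an external step and is not run here.

    Per-replicate failures are logged in the ``status`` column, never
    silently dropped.
    """
    chain = chain or ChainConfig(n_steps=20_000, burnin=2_000, thin=10)
    ss = np.random.SeedSequence(seed)
    rows = []

    def scheme_of(tag: str):
        if tag == "lognormal":
            return SamplingScheme(kind="lognormal")
        return SamplingScheme(kind="fixed_k", k=int(tag))

    if experiment == "depth":
        conditions = [("depth", d) for d in depths]
    elif experiment == "sampling":
        conditions = [("scheme", s) for s in schemes]
    elif experiment == "seqlen":
        conditions = [("seqlen", None)]
    else:
        raise ValueError(f"unknown experiment {experiment!r}")

    for cond_name, cond_val in conditions:
        for rep in range(replicates):
            child = ss.spawn(1)[0]
            states = child.generate_state(4) % (2**31)
            row = dict(experiment=experiment, replicate=rep, status="ok")
            try:
                if experiment == "depth":
                    depth = float(cond_val)
                    row["depth"] = depth
                    sp = simulate_yule_species_tree(
                        n_species_grow, n_species, depth, int(states[0])
                    )
                    gt = simulate_msc_gene_tree(
                        sp,
                        np.full(n_species, alleles_per_species),
                        seed=int(states[1]),
                    )
                    row.update(_fit_one(gt, chain, int(states[2])))
                elif experiment == "sampling":
                    row["scheme"] = cond_val
                    sp = simulate_yule_species_tree(
                        n_species_grow, n_species, 80.0, int(states[0])
                    )
                    gt = simulate_msc_gene_tree(
                        sp, scheme_of(cond_val), seed=int(states[1])
                    )
                    row["n_alleles"] = gt.n_tips
                    row.update(_fit_one(gt, chain, int(states[2])))
                else:  # seqlen
                    sp = simulate_yule_species_tree(
                        n_species_grow, n_species, 160.0, int(states[0])
                    )
                    gt = simulate_msc_gene_tree(
                        sp,
                        np.full(n_species, alleles_per_species),
                        seed=int(states[1]),
                    )
                    fit = _fit_one(gt, chain, int(states[2]))
                    for L in seq_lengths:
                        seqs = simulate_sequences(
                            gt, SeqSimConfig(length=int(L)), int(states[3])
                        )
                        uniq = len(set(seqs.values()))
                        rows.append(
                            dict(
                                experiment=experiment,
                                replicate=rep,
                                status="ok",
                                seq_length=int(L),
                                n_unique_sequences=uniq,
                                **fit,
                            )
                        )
                    continue
            except Exception as exc:
                warnings.warn(f"replicate failed ({cond_name}={cond_val}): {exc}")
                row["status"] = f"failed: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def experiment_manifest(args: dict, seed: int) -> str:
    """JSON manifest (full config + seed) for an experiment run."""
    payload = {"seed": seed, **{k: _jsonable(v) for k, v in args.items()}}
    return json.dumps(payload, indent=2, sort_keys=True)


def _jsonable(v):
    if isinstance(v, (ChainConfig, SamplingScheme, IslandModelConfig, SeqSimConfig)):
        return asdict(v)
    if isinstance(v, (np.ndarray, tuple)):
        return list(v)
    return v
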