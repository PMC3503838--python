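"""Ultrametric tree handling and threshold decomposition.

The GMYC likelihood consumes an ultrametric, rooted, binary gene tree as a
table of waiting times between successive branching events, with per-interval
lineage counts split between one interspecific (Yule) process and ``k``
within-species coalescent processes.  This module owns the tree data model,
Newick/NEXUS ingestion (via dendropy), ultrametricity validation, and the
decomposition of a (tree, threshold) pair into those counts.

Threshold convention
--------------------
The threshold is a rank ``T`` in ``{2..n_tips}``: the ``T - 1`` oldest
branching events are classified as speciations, so exactly ``T`` lineages
cross the threshold and the tree is partitioned into ``T`` entities.  Node
ages are measured backward from the present (tips at age 0, root oldest); the
reported "threshold time" is the age of the ``T - 1``-th ranked event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .errors import TreeParseError, TreeValidationError

__all__ = [
    "UltrametricTree",
    "SpeciesPartition",
    "IntervalTable",
    "ThresholdCounts",
    "read_trees",
    "write_trees",
    "ranked_branching_times",
    "partition_at",
    "interval_table",
    "threshold_counts",
]

DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class UltrametricTree:
    """A rooted, binary, ultrametric tree stored as parent/age arrays.

    Nodes ``0..n_tips-1`` are tips (age exactly 0.0); nodes
    ``n_tips..2*n_tips-2`` are internal.  ``parent[root] == -1``.  Branch
    lengths are implied: ``age[parent[v]] - age[v]``.

    Parameters
    ----------
    parent : array of int
        Parent node id per node (root has -1).
    age : array of float
        Node age (time before present); tips must be 0.
    labels : sequence of str
        Tip labels, ``labels[i]`` names tip ``i``; must be unique.
    units : str
        Free-text declaration of the branch-length time units
        (e.g. ``"N_generations"``, ``"substitutions_per_site"``).  Recorded
        as metadata; never rescaled silently.
    """

    def __init__(self, parent, age, labels, units: str = "unknown",
                 min_tips: int = 3):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.age = np.asarray(age, dtype=np.float64)
        self.labels = list(labels)
        self.units = units
        self.n_tips = len(self.labels)
        if len(set(self.labels)) != self.n_tips:
            raise TreeValidationError("tip labels are not unique")
        # analysis trees need >= 3 tips (no inter-event waiting time exists
        # for fewer); simulators may construct bare cherries with min_tips=2
        if self.n_tips < max(min_tips, 2):
            raise TreeValidationError(
                "need at least 3 tips (no inter-event waiting time exists "
                "for fewer)"
            )
        if self.parent.shape[0] != 2 * self.n_tips - 1:
            raise TreeValidationError("tree is not binary (wrong node count)")
        self._index: _TreeIndex | None = None
        self._validate_structure()

    # ------------------------------------------------------------------
    def _validate_structure(self) -> None:
        n = self.n_tips
        if np.any(self.age[:n] != 0.0):
            raise TreeValidationError("tip ages must be exactly 0")
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise TreeValidationError("tree must have exactly one root")
        self.root = int(roots[0])
        ok = np.ones(self.parent.shape[0], dtype=bool)
        ok[self.root] = False
        par = self.parent[ok]
        if np.any(self.age[par] - self.age[ok] < 0):
            raise TreeValidationError("negative branch length (child older than parent)")
        internal_ages = self.age[n:]
        if np.any(internal_ages <= 0.0):
            raise TreeValidationError(
                "internal node at age <= 0; ties with tips are not allowed "
                "(deduplicate identical sequences, or pass jitter=True)"
            )
        order = np.argsort(-internal_ages, kind="stable")
        ranked = internal_ages[order]
        if np.any(np.diff(ranked) >= 0.0):
            raise TreeValidationError(
                "tied node ages detected; the model cannot attribute "
                "zero-length waiting times.  Deduplicate identical sequences "
                "or pass jitter=True to perturb ties."
            )

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_dendropy(
        cls,
        dtree: dendropy.Tree,
        units: str = "unknown",
        rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
        jitter: bool = False,
    ) -> "UltrametricTree":
        """Build from a dendropy tree, validating and renormalizing ages.

        Root-to-tip path lengths must agree within relative tolerance
        ``rtol``; tips are then pinned to age 0 and internal ages set to
        ``mean tip depth - node depth``.  Polytomies are resolved into
        zero-length branches and handled by the tie rule (requires
        ``jitter=True``).
        """
        dtree = dtree.clone(depth=1)
        dtree.resolve_polytomies(update_bipartitions=False)
        dtree.calc_node_root_distances(return_leaf_distances_only=False)
        leaves = list(dtree.leaf_node_iter())
        if len(leaves) < 3:
            raise TreeValidationError("need at least 3 tips")
        depths = np.array([lf.root_distance for lf in leaves], dtype=float)
        scale = depths.max()
        if scale <= 0:
            raise TreeValidationError("tree has zero depth")
        rel_err = (depths.max() - depths.min()) / scale
        if rel_err > rtol:
            worst_lo = leaves[int(np.argmin(depths))].taxon.label
            worst_hi = leaves[int(np.argmax(depths))].taxon.label
            raise TreeValidationError(
                f"tree is not ultrametric: root-to-tip depths differ by "
                f"relative error {rel_err:.3g} (> {rtol:.1g}); worst tip pair "
                f"{worst_lo!r} ({depths.min():.6g}) vs {worst_hi!r} "
                f"({depths.max():.6g})"
            )
        depth0 = depths.mean()

        nodes = list(dtree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        n = len(tips)
        ids: dict[int, int] = {}
        labels = []
        for i, nd in enumerate(tips):
            ids[id(nd)] = i
            labels.append(nd.taxon.label if nd.taxon is not None else f"t{i}")
        for j, nd in enumerate(internals):
            ids[id(nd)] = n + j
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        age = np.zeros(2 * n - 1, dtype=float)
        for nd in nodes:
            v = ids[id(nd)]
            if nd.parent_node is not None:
                parent[v] = ids[id(nd.parent_node)]
            if not nd.is_leaf():
                age[v] = depth0 - nd.root_distance
        age[:n] = 0.0
        if jitter:
            age = _resolve_ties(parent, age, n)
        return cls(parent, age, labels, units=units)

    @classmethod
    def from_newick(
        cls,
        newick: str,
        units: str = "unknown",
        rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
        jitter: bool = False,
    ) -> "UltrametricTree":
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeParseError(f"could not parse newick: {exc}") from exc
        return cls.from_dendropy(dtree, units=units, rtol=rtol, jitter=jitter)

    # -- exports --------------------------------------------------------
    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace(self.labels)
        dtree = dendropy.Tree(taxon_namespace=tns)
        n_total = 2 * self.n_tips - 1
        dnodes = [dendropy.Node() for _ in range(n_total)]
        for i, lab in enumerate(self.labels):
            dnodes[i].taxon = tns.get_taxon(lab)
        for v in range(n_total):
            p = self.parent[v]
            if p >= 0:
                dnodes[p].add_child(dnodes[v])
                dnodes[v].edge.length = float(self.age[p] - self.age[v])
        dtree.seed_node = dnodes[self.root]
        return dtree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick").strip()

    # -- topology helpers ----------------------------------------------
    @property
    def index(self) -> "_TreeIndex":
        if self._index is None:
            self._index = _TreeIndex(self)
        return self._index

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(2 * self.n_tips - 1)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(v)
        return kids

    @property
    def root_age(self) -> float:
        return float(self.age[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Branch length above every non-root node."""
        mask = self.parent >= 0
        out = np.zeros(self.parent.shape[0])
        out[mask] = self.age[self.parent[mask]] - self.age[mask]
        return out[mask]

    def mrca_age_matrix(self) -> np.ndarray:
        """n_tips x n_tips matrix of pairwise MRCA ages (0 on the diagonal)."""
        idx = self.index
        n = self.n_tips
        out = np.zeros((n, n))
        # For each internal node (young to old), stamp pairs across its
        # children's tip sets; youngest common ancestor stamps first.
        for r in range(idx.m - 1, -1, -1):
            v = idx.node_of_rank[r]
            kid_tips = [idx.tips_under(c) for c in idx.kids[v]]
            for a in kid_tips[0]:
                for b in kid_tips[1]:
                    out[a, b] = out[b, a] = idx.t[r]
        return out


def _resolve_ties(parent: np.ndarray, age: np.ndarray, n: int) -> np.ndarray:
    """Perturb tied/zero-gap internal ages deterministically.

    Perturbations are bounded by ~1e-8 x root age: first enforce
    ``age[child] < age[parent]`` top-down, then break exact ties among
    unrelated nodes.
    """
    age = age.copy()
    root_age = age.max()
    eps = 1e-8 * root_age
    order = np.argsort(-age[n:], kind="stable") + n  # internals, old -> young
    for _ in range(len(order) + 1):
        changed = False
        for v in order:
            p = parent[v]
            if p >= 0 and age[v] >= age[p]:
                age[v] = age[p] - eps
                changed = True
        if not changed:
            break
    # exact ties among unrelated internals
    tiny = eps * 1e-3
    for _ in range(len(order) + 1):
        internal_ages = age[n:]
        srt = np.sort(internal_ages)
        if np.all(np.diff(srt) > 0):
            break
        seen: dict[float, int] = {}
        for v in order:
            a = float(age[v])
            if a in seen:
                seen[a] += 1
                age[v] = a - tiny * seen[a]
            else:
                seen[a] = 0
    age[age <= 0] = np.nan  # will fail validation loudly rather than silently
    age[:n] = 0.0
    return age


# ---------------------------------------------------------------------------
# internal rank/subtree index
# ---------------------------------------------------------------------------


class _TreeIndex:
    """Rank-ordered view of a tree's internal nodes plus subtree tables.

    rank 0 is the root (oldest event); ``t`` holds ages in strictly
    decreasing order; ``x[q] = t[q] - t[q+1]`` is the waiting time of the
    0-indexed inter-event interval ``q`` (which contains ``q + 2`` lineages).
    """

    def __init__(self, tree: UltrametricTree):
        self.tree = tree
        n = tree.n_tips
        self.m = n - 1
        internal_ids = np.arange(n, 2 * n - 1)
        order = np.argsort(-tree.age[internal_ids], kind="stable")
        self.node_of_rank = internal_ids[order]
        self.rank_of_node = {int(v): r for r, v in enumerate(self.node_of_rank)}
        self.t = tree.age[self.node_of_rank].copy()
        self.x = -np.diff(self.t)
        self.kids = tree.children()
        # subtree internal ranks (ascending, inclusive) and tip sets
        self.sub_ranks: list[np.ndarray] = [None] * self.m  # type: ignore
        self._tips: list[list[int]] = [None] * self.m  # type: ignore
        for r in range(self.m - 1, -1, -1):
            v = self.node_of_rank[r]
            ranks = [r]
            tips: list[int] = []
            for c in self.kids[v]:
                if c < n:
                    tips.append(c)
                else:
                    cr = self.rank_of_node[c]
                    ranks.extend(self.sub_ranks[cr].tolist())
                    tips.extend(self._tips[cr])
            self.sub_ranks[r] = np.array(sorted(ranks), dtype=np.int64)
            self._tips[r] = tips

    def tips_under(self, node: int) -> list[int]:
        if node < self.tree.n_tips:
            return [node]
        return self._tips[self.rank_of_node[node]]

    def n_tips_under_rank(self, r: int) -> int:
        return len(self._tips[r])


# ---------------------------------------------------------------------------
# partitions and interval tables
# ---------------------------------------------------------------------------


@dataclass
class SpeciesPartition:
    """Tips -> entity labels implied by a (tree, threshold) pair.

    An entity with >= 2 tips is a *cluster* (it carries a coalescent
    process); an entity with a single tip is a *singleton*.
    """

    assignment: dict[str, str]
    n_entities: int
    n_clusters: int
    n_singletons: int

    def to_csv(self, path_or_buf) -> None:
        import pandas as pd

        pd.DataFrame(
            {"tip": list(self.assignment), "entity": list(self.assignment.values())}
        ).to_csv(path_or_buf, index=False)


@dataclass
class ThresholdCounts:
    """Per-interval lineage counts for one (tree, threshold) pair.

    This is the sparse form the likelihood consumes.  0-indexed interval
    ``q`` spans ages ``[t[q+1], t[q]]``, has waiting time ``x[q]`` and
    ``q + 2`` total lineages.  ``A[q]`` of them belong to the interspecific
    (Yule) process; within-cluster lineage products ``n(n-1)`` are stored
    sparsely as (interval, value) pairs.

    Rate factors under the exposure-matched event-attribution convention:
    the ``E_y`` Yule events with an observed preceding waiting interval
    contribute ``sum log(count) = S_ylog`` (at p = 1 scale; the general term
    is ``p * log count``) and the ``E_c`` coalescent events with an observed
    waiting interval contribute ``S_clog`` likewise.
    """

    T: int
    n_tips: int
    t: np.ndarray
    x: np.ndarray
    A: np.ndarray
    pair_q: np.ndarray
    pair_prod: np.ndarray
    E_y: int
    S_ylog: float
    E_c: int
    S_clog: float
    cluster_ranks: np.ndarray
    entity_roots: list[int]
    n_singletons: int
    threshold_time: float

    @property
    def m(self) -> int:
        return self.n_tips - 1

    def coal_counts_dense(self) -> np.ndarray:
        """(m-1) x n_clusters matrix of within-cluster lineage counts."""
        m1 = self.m - 1
        k = len(self.cluster_ranks)
        out = np.zeros((m1, k), dtype=np.int64)
        rank_col = {int(r): j for j, r in enumerate(self.cluster_ranks)}
        # reconstruct counts from products: n(n-1) = prod -> n
        offset = 0
        for j, rw in enumerate(self.cluster_ranks):
            span = m1 - int(rw)
            prods = self.pair_prod[offset : offset + span]
            qs = self.pair_q[offset : offset + span]
            ns = np.rint((1 + np.sqrt(1 + 4 * prods)) / 2).astype(np.int64)
            out[qs, rank_col[int(rw)]] = ns
            offset += span
        return out


@dataclass
class IntervalTable:
    """Dense waiting-time/lineage-count table for inspection and export.

    Invariants: ``sum(waiting_times) == t[0] - t[-1]``; in 0-indexed interval
    ``q``, ``n_yule[q] + coal_counts[q].sum() == q + 2`` (the stem of a
    not-yet-branched cluster is carried by the Yule process; a cluster's
    within-species lineage count is 0 until its own MRCA).
    """

    ranked_node_ages: np.ndarray
    waiting_times: np.ndarray
    n_yule: np.ndarray
    coal_counts: np.ndarray  # (m-1) x k
    threshold: int
    threshold_time: float

    @property
    def total_lineages(self) -> np.ndarray:
        return np.arange(2, 2 + len(self.waiting_times))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def ranked_branching_times(tree: UltrametricTree) -> np.ndarray:
    """Strictly decreasing internal node ages, length ``n_tips - 1``."""
    return tree.index.t.copy()


def _check_T(tree: UltrametricTree, T: int, allow_null: bool = False) -> int:
    lo = 1 if allow_null else 2
    T = int(T)
    if not (lo <= T <= tree.n_tips):
        raise ValueError(
            f"threshold rank T={T} outside [{lo}, {tree.n_tips}] for a "
            f"{tree.n_tips}-tip tree"
        )
    return T


def _entity_roots(tree: UltrametricTree, T: int) -> tuple[list[int], list[int]]:
    """(cluster ranks, singleton tip ids) for threshold rank T (T >= 1)."""
    idx = tree.index
    n = tree.n_tips
    if T == 1:
        return [0], []
    clusters: list[int] = []
    singles: list[int] = []
    for r in range(T - 1):  # speciation ranks 0..T-2
        v = idx.node_of_rank[r]
        for c in idx.kids[v]:
            if c < n:
                singles.append(c)
            else:
                cr = idx.rank_of_node[c]
                if cr > T - 2:
                    clusters.append(cr)
    return sorted(clusters), singles


def threshold_counts(
    tree: UltrametricTree, T: int, allow_null: bool = False
) -> ThresholdCounts:
    """Decompose a tree at threshold rank ``T`` into likelihood counts.

    ``T = 1`` (whole tree a single coalescent process, the null model) is
    permitted only with ``allow_null=True``.
    """
    if tree.n_tips < 3:
        raise TreeValidationError(
            "threshold decomposition needs >= 3 tips"
        )
    T = _check_T(tree, T, allow_null=allow_null)
    idx = tree.index
    m = idx.m
    m1 = m - 1
    clusters, singles = _entity_roots(tree, T)
    cluster_ranks = np.array(clusters, dtype=np.int64)
    n_singletons = len(singles)

    q = np.arange(m1)
    stems = len(clusters) - np.searchsorted(cluster_ranks, q, side="right")
    A = np.where(q <= T - 2, q + 2, n_singletons + stems).astype(np.int64)

    pair_q_parts = []
    pair_prod_parts = []
    S_clog = 0.0
    for rw in clusters:
        sub = idx.sub_ranks[rw]
        qs = np.arange(rw, m1)
        cnt = np.searchsorted(sub, qs, side="right").astype(np.float64)
        counts = cnt + 1.0
        pair_q_parts.append(qs)
        pair_prod_parts.append(counts * (counts - 1.0))
        s_w = len(sub)  # events in this cluster
        js = np.arange(s_w)
        if sub[-1] == m - 1:  # globally youngest event: no observed segment
            js = js[:-1]
        S_clog += float(np.sum(np.log((js + 2.0) * (js + 1.0))))
    if pair_q_parts:
        pair_q = np.concatenate(pair_q_parts)
        pair_prod = np.concatenate(pair_prod_parts)
    else:
        pair_q = np.empty(0, dtype=np.int64)
        pair_prod = np.empty(0)

    E_y = max(0, T - 2)
    # Yule factor events are ranks 2..T-1 (1-indexed); event e sees count e
    S_ylog = float(np.sum(np.log(np.arange(2, T)))) if T >= 3 else 0.0
    if T == tree.n_tips:
        E_c = 0
    else:
        E_c = m - T if T >= 2 else m - 1
    threshold_time = float(idx.t[T - 2]) if T >= 2 else float("inf")

    entity_roots = [int(idx.node_of_rank[r]) for r in clusters] + list(singles)
    return ThresholdCounts(
        T=T,
        n_tips=tree.n_tips,
        t=idx.t,
        x=idx.x,
        A=A,
        pair_q=pair_q,
        pair_prod=pair_prod,
        E_y=E_y,
        S_ylog=S_ylog,
        E_c=E_c,
        S_clog=S_clog,
        cluster_ranks=cluster_ranks,
        entity_roots=entity_roots,
        n_singletons=n_singletons,
        threshold_time=threshold_time,
    )


def partition_at(tree: UltrametricTree, T: int) -> SpeciesPartition:
    """Species partition implied by cutting the tree at threshold rank T."""
    T = _check_T(tree, T)
    idx = tree.index
    clusters, singles = _entity_roots(tree, T)
    assignment: dict[str, str] = {}
    eid = 0
    n_clusters = 0
    for rw in clusters:
        eid += 1
        n_clusters += 1
        for tip in idx._tips[rw]:
            assignment[tree.labels[tip]] = f"sp{eid}"
    for tip in singles:
        eid += 1
        assignment[tree.labels[tip]] = f"sp{eid}"
    return SpeciesPartition(
        assignment=assignment,
        n_entities=eid,
        n_clusters=n_clusters,
        n_singletons=len(singles),
    )


def interval_table(tree: UltrametricTree, T: int) -> IntervalTable:
    """Dense per-interval lineage-count table at threshold rank T."""
    tc = threshold_counts(tree, T)
    return IntervalTable(
        ranked_node_ages=tc.t.copy(),
        waiting_times=tc.x.copy(),
        n_yule=tc.A.copy(),
        coal_counts=tc.coal_counts_dense(),
        threshold=T,
        threshold_time=tc.threshold_time,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_trees(
    path,
    format: str = "newick",
    burnin_fraction: float = 0.0,
    thin: int = 1,
    units: str = "unknown",
    rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
    jitter: bool = False,
) -> list[UltrametricTree]:
    """Read trees from a Newick or NEXUS file (``.trees`` dialect included).

    Burn-in trees (``floor(burnin_fraction * n)``) are dropped before
    thinning; every ``thin``-th remaining tree is kept, starting with the
    first.  Each tree is validated as ultrametric (within ``rtol``) and
    renormalized.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"format must be 'newick' or 'nexus', got {format!r}")
    if not (0.0 <= burnin_fraction < 1.0):
        raise ValueError("burnin_fraction must be in [0, 1)")
    if thin < 1:
        raise ValueError("thin must be a positive integer")
    try:
        tlist = dendropy.TreeList.get(path=str(path), schema=format)
    except Exception as exc:
        raise TreeParseError(f"could not parse {path}: {exc}") from exc
    n_burn = int(len(tlist) * burnin_fraction)
    kept = list(tlist)[n_burn:][::thin]
    return [
        UltrametricTree.from_dendropy(dt, units=units, rtol=rtol, jitter=jitter)
        for dt in kept
    ]


def write_trees(trees: Sequence[UltrametricTree], path, format: str = "newick") -> None:
    """Write trees to Newick (one per line) or a NEXUS trees block."""
    tns = dendropy.TaxonNamespace(trees[0].labels)
    tlist = dendropy.TreeList(taxon_namespace=tns)
    for tr in trees:
        tlist.append(tr.to_dendropy(taxon_namespace=tns))
    tlist.write(path=str(path), schema=format)
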