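"""Posterior and ML summaries: species numbers, HPDs, co-conspecificity.

The posterior over the threshold rank is a discrete distribution over the
number of delimited entities; its 95% HPD is defined here as the smallest
contiguous integer interval holding >= 95% of the mass (threshold rank is
ordinal).  Pairwise co-conspecificity marginalizes species assignments over
both model parameters and (when chains were run on a tree sample)
phylogenetic uncertainty: two sequences are conspecific in a retained sample
iff their MRCA on that sample's tree is younger than the sample's threshold
time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import Trace
from .core import MLScanResult
from .trees import SpeciesPartition, UltrametricTree

__all__ = [
    "SpeciesNumberSummary",
    "CoConspecificityMatrix",
    "species_number_summary",
    "coconspecificity",
    "consensus_partition",
    "compare_akaike_posterior",
]


@dataclass
class SpeciesNumberSummary:
    """Posterior summary of the number of delimited entities."""

    mean: float
    mode: int
    hpd_lower: int
    hpd_upper: int
    pmf: pd.Series
    per_tree: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "mode": int(self.mode),
            "hpd_95": [int(self.hpd_lower), int(self.hpd_upper)],
            "pmf": {int(k): float(v) for k, v in self.pmf.items()},
        }


def discrete_hpd(values: np.ndarray, mass: float = 0.95) -> tuple[int, int]:
    """Smallest contiguous integer interval with at least ``mass`` mass.

    Ties are broken toward the narrower interval, then toward smaller
    values.
    """
    values = np.asarray(values, dtype=np.int64)
    lo, hi = int(values.min()), int(values.max())
    support = np.arange(lo, hi + 1)
    pmf = np.bincount(values - lo, minlength=len(support)) / len(values)
    cum = np.concatenate([[0.0], np.cumsum(pmf)])
    best = None
    for a in range(len(support)):
        # smallest b >= a with cum[b+1] - cum[a] >= mass
        target = mass + cum[a]
        b = int(np.searchsorted(cum, target - 1e-12, side="left")) - 1
        if b >= len(support):
            continue
        if cum[b + 1] - cum[a] < mass - 1e-12:
            continue
        width = b - a
        key = (width, a)
        if best is None or key < best[0]:
            best = (key, (lo + a, lo + b))
    assert best is not None
    return best[1]


def species_number_summary(trace: Trace, mass: float = 0.95) -> SpeciesNumberSummary:
    """Mean, mode, contiguous HPD and full PMF of the species number."""
    if len(trace.samples) == 0:
        raise ValueError("empty trace")
    ns = trace.samples["n_species"].to_numpy()
    lo, hi = discrete_hpd(ns, mass)
    counts = trace.samples["n_species"].value_counts().sort_index()
    pmf = counts / counts.sum()
    per_tree = (
        trace.samples.groupby("tree_id")["n_species"]
        .agg(["mean", "min", "max", "count"])
        .reset_index()
    )
    return SpeciesNumberSummary(
        mean=float(ns.mean()),
        mode=int(pmf.idxmax()),
        hpd_lower=lo,
        hpd_upper=hi,
        pmf=pmf,
        per_tree=per_tree,
    )


@dataclass
class CoConspecificityMatrix:
    """Symmetric tip x tip matrix of marginal conspecificity probabilities."""

    probs: np.ndarray
    labels: list[str]

    def __post_init__(self):
        assert self.probs.shape == (len(self.labels), len(self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.labels, columns=self.labels)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf)

    def reordered(self, order: list[str]) -> "CoConspecificityMatrix":
        idx = [self.labels.index(lab) for lab in order]
        return CoConspecificityMatrix(self.probs[np.ix_(idx, idx)], list(order))


def coconspecificity(
    trace: Trace, trees: list[UltrametricTree] | UltrametricTree
) -> CoConspecificityMatrix:
    """Marginal probability that each tip pair is conspecific.

    ``trees[i]`` must be the tree behind chain ``tree_id == i``.  For each
    retained sample, tips are conspecific iff their MRCA age on that
    sample's tree is below the sample's threshold time; probabilities are
    the fraction over all pooled samples.
    """
    if isinstance(trees, UltrametricTree):
        trees = [trees]
    tipset = tuple(sorted(trees[0].labels))
    for tr in trees[1:]:
        if tuple(sorted(tr.labels)) != tipset:
            raise ValueError("trees have differing tip sets")
    labels = list(tipset)
    n = len(labels)
    total = np.zeros((n, n))
    n_samples = 0
    for tree_id, grp in trace.samples.groupby("tree_id"):
        tree = trees[int(tree_id)]
        order = [tree.labels.index(lab) for lab in labels]
        mrca = tree.mrca_age_matrix()[np.ix_(order, order)]
        thr = np.sort(grp["threshold_time"].to_numpy())
        # count of samples whose threshold is older than the pair's MRCA
        cnt = len(thr) - np.searchsorted(thr, mrca.ravel(), side="right")
        total += cnt.reshape(n, n)
        n_samples += len(thr)
    probs = total / n_samples
    np.fill_diagonal(probs, 1.0)
    return CoConspecificityMatrix(probs=probs, labels=labels)


def consensus_partition(
    matrix: CoConspecificityMatrix, cutoff: float = 0.95
) -> tuple[SpeciesPartition, list[tuple[str, str]]]:
    """Single-linkage consensus clusters of pairs with prob >= cutoff.

    Returns the partition plus a conflict report: same-cluster pairs whose
    marginal probability is below the cutoff (single linkage above 0.5 can
    be non-transitive).  This is a lossy export convenience relative to the
    marginal matrix.
    """
    if not 0.5 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0.5, 1]")
    n = len(matrix.labels)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.probs[i, j] >= cutoff:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    assignment: dict[str, str] = {}
    conflicts: list[tuple[str, str]] = []
    n_clusters = n_singletons = 0
    for eid, members in enumerate(sorted(groups.values(), key=lambda g: g[0])):
        name = f"sp{eid + 1}"
        if len(members) > 1:
            n_clusters += 1
        else:
            n_singletons += 1
        for i in members:
            assignment[matrix.labels[i]] = name
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                if matrix.probs[i, j] < cutoff:
                    conflicts.append((matrix.labels[i], matrix.labels[j]))
    part = SpeciesPartition(
        assignment=assignment,
        n_entities=len(groups),
        n_clusters=n_clusters,
        n_singletons=n_singletons,
    )
    return part, conflicts


def compare_akaike_posterior(ml: MLScanResult, trace: Trace) -> pd.DataFrame:
    """Per-threshold table of Akaike weights vs posterior probabilities.

    Both columns sum to 1 over the union of threshold values.
    """
    w = ml.akaike_weights
    post = trace.samples["T"].value_counts(normalize=True).sort_index()
    ts = sorted(set(w.index.astype(int)) | set(post.index.astype(int)))
    out = pd.DataFrame(
        {
            "T": ts,
            "akaike_weight": [float(w.get(t, 0.0)) for t in ts],
            "posterior_prob": [float(post.get(t, 0.0)) for t in ts],
        }
    )
    return out


def entropy(probs) -> float:
    """Shannon entropy (nats) of a discrete distribution, ignoring zeros."""
    p = np.asarray(probs, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def plot_coconspecificity(
    matrix: CoConspecificityMatrix,
    reference_tree: UltrametricTree | None = None,
    path=None,
):
    """Heatmap of the co-conspecificity matrix, tips ordered by a tree.

    Ordering by a reference tree's tip sequence makes off-diagonal
    probability structure (uncertainty owed to topology) visible.  Requires
    matplotlib (the ``plot`` extra); returns the figure, and writes it to
    ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = matrix
    if reference_tree is not None:
        idx = reference_tree.index
        order = [
            reference_tree.labels[tip]
            for tip in idx.tips_under(reference_tree.root)
        ]
        mat = matrix.reordered(order)
    fig, ax = plt.subplots(figsize=(8, 8))
    im = ax.imshow(mat.probs, cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(mat.labels)))
    ax.set_yticks(range(len(mat.labels)))
    small = len(mat.labels) <= 40
    ax.set_xticklabels(mat.labels if small else [""] * len(mat.labels),
                       rotation=90, fontsize=6)
    ax.set_yticklabels(mat.labels if small else [""] * len(mat.labels),
                       fontsize=6)
    fig.colorbar(im, ax=ax, label="P(conspecific)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
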