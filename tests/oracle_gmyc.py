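"""Independent brute-force GMYC oracle used only by the test suite.

Re-derives interval lineage counts by geometric slicing of a dendropy tree
(no rank arithmetic shared with the package): every branch is classified by
comparing its parent node's age with a continuous cut time placed inside the
threshold gap, and per-interval counts are obtained by testing each branch's
presence in each inter-event time slice.  Deliberately O(n^2) and simple.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np
from scipy import optimize


class OracleTree:
    def __init__(self, newick: str):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        leaves = list(tree.leaf_node_iter())
        depth = max(lf.root_distance for lf in leaves)
        self.nodes = list(tree.preorder_node_iter())
        for nd in self.nodes:
            nd.age_o = 0.0 if nd.is_leaf() else depth - nd.root_distance
        self.internals = sorted(
            (nd for nd in self.nodes if not nd.is_leaf()),
            key=lambda nd: -nd.age_o,
        )
        self.ages = [nd.age_o for nd in self.internals]  # t_1..t_m descending
        self.m = len(self.ages)
        self.n_tips = len(leaves)
        self.labels = sorted(lf.taxon.label for lf in leaves)

    # -- helpers --------------------------------------------------------
    def cut_time(self, T: int) -> float:
        if T == 1:
            return self.ages[0] * 2 + 1.0  # above the root: no speciations
        if T == self.n_tips:
            return self.ages[-1] / 2.0
        return (self.ages[T - 2] + self.ages[T - 1]) / 2.0

    def _parent_age(self, nd) -> float:
        return math.inf if nd.parent_node is None else nd.parent_node.age_o

    def _present(self, nd, s: float) -> bool:
        """Is the branch above `nd` present at time s?"""
        return nd.age_o <= s < self._parent_age(nd)

    def _crossing_ancestor(self, nd, cut: float):
        """The node whose parent branch crosses the cut, from nd upward."""
        while self._parent_age(nd) < cut:
            nd = nd.parent_node
        return nd

    def entities(self, T: int) -> dict[str, frozenset]:
        cut = self.cut_time(T)
        groups: dict[int, set[str]] = {}
        for nd in self.nodes:
            if nd.is_leaf():
                anc = self._crossing_ancestor(nd, cut)
                groups.setdefault(id(anc), set()).add(nd.taxon.label)
        return {min(v): frozenset(v) for v in groups.values()}

    def interval_counts(self, T: int):
        """Per 0-indexed interval q: (x_q, A_q, {entity: count}) by slicing."""
        if not hasattr(self, "_ic_cache"):
            self._ic_cache = {}
        if T in self._ic_cache:
            return self._ic_cache[T]
        cut = self.cut_time(T)
        out = []
        for q in range(self.m - 1):
            top, bot = self.ages[q], self.ages[q + 1]
            s = (top + bot) / 2.0
            A = 0
            coal: dict[int, int] = {}
            for nd in self.nodes:
                if nd.parent_node is None or not self._present(nd, s):
                    continue
                if self._parent_age(nd) > cut:
                    A += 1
                else:
                    anc = self._crossing_ancestor(nd, cut)
                    coal[id(anc)] = coal.get(id(anc), 0) + 1
            out.append((top - bot, A, coal))
        self._ic_cache[T] = out
        return out

    def factors(self, T: int):
        """(yule_counts, coal_pair_products) of the attributable events.

        A Yule event of rank e (2..T-1) sees the lineage count of the
        interval it terminates; a coalescent event of rank e (T..m-1) sees
        its own entity's count just below itself.
        """
        cut = self.cut_time(T)
        yule_counts = []
        coal_prods = []
        for e in range(2, self.m + 1):  # 1-indexed event ranks with segments
            nd = self.internals[e - 1]
            if nd.age_o > cut:  # Yule event
                s = (self.ages[e - 2] + self.ages[e - 1]) / 2.0
                cnt = sum(
                    1
                    for x in self.nodes
                    if x.parent_node is not None and self._present(x, s)
                )
                yule_counts.append(cnt)
        for e in range(1, self.m):  # coalescent events with observed segment
            nd = self.internals[e - 1]
            if nd.age_o < cut:
                s = (self.ages[e - 1] + self.ages[e]) / 2.0
                anc = self._crossing_ancestor(nd, cut)
                n = 0
                for x in self.nodes:
                    if x.parent_node is None or not self._present(x, s):
                        continue
                    if self._parent_age(x) < cut and (
                        self._crossing_ancestor(x, cut) is anc
                    ):
                        n += 1
                coal_prods.append(n * (n - 1))
        return yule_counts, coal_prods

    # -- likelihood -----------------------------------------------------
    def loglik(self, T, p_y, p_c, lam_y, lam_c) -> float:
        """Attribution-convention log likelihood by direct summation."""
        total = 0.0
        for x, A, coal in self.interval_counts(T):
            b = lam_y * A**p_y if A > 0 else 0.0
            for n in coal.values():
                if n > 1:
                    b += lam_c * (n * (n - 1)) ** p_c
            total += -b * x
        yule_counts, coal_prods = self.factors(T)
        for c in yule_counts:
            total += math.log(lam_y * c**p_y)
        for pr in coal_prods:
            total += math.log(lam_c * pr**p_c)
        return total

    def loglik_strict(self, T, p_y, p_c, lam_y, lam_c) -> float:
        """Plain combined-hazard density b * exp(-b x) per interval."""
        total = 0.0
        for x, A, coal in self.interval_counts(T):
            b = lam_y * A**p_y if A > 0 else 0.0
            for n in coal.values():
                if n > 1:
                    b += lam_c * (n * (n - 1)) ** p_c
            if b <= 0:
                return -math.inf
            total += math.log(b) - b * x
        return total

    def _ab_coefs(self, T, p_y, p_c):
        a = []
        c = []
        xs = []
        for x, A, coal in self.interval_counts(T):
            a.append(A**p_y if A > 0 else 0.0)
            c.append(sum((n * (n - 1)) ** p_c for n in coal.values() if n > 1))
            xs.append(x)
        return np.array(a), np.array(c), np.array(xs)

    def numeric_profile_strict(self, T, p_y, p_c):
        """Numerically maximize the combined loglik over the two rates."""
        a, c, xs = self._ab_coefs(T, p_y, p_c)

        def neg(v):
            ly, lc = np.exp(v)
            b = ly * a + lc * c
            if np.any(b <= 0):
                return math.inf
            return -(np.sum(np.log(b)) - ly * (a @ xs) - lc * (c @ xs))

        best = None
        for start in ([0.0, 0.0], [2.0, -2.0], [-2.0, 2.0]):
            res = optimize.minimize(neg, start, method="Nelder-Mead",
                                    options={"xatol": 1e-11, "fatol": 1e-12,
                                             "maxiter": 20000})
            if best is None or res.fun < best.fun:
                best = res
        ly, lc = np.exp(best.x)
        if not a.any():
            ly = math.nan
        if not c.any():
            lc = math.nan
        return ly, lc, -best.fun

    def profile_strict_loglik(self, T, p_y, p_c) -> float:
        a, c, xs = self._ab_coefs(T, p_y, p_c)
        if not c.any():
            u = len(xs) / (a @ xs)
            return float(np.sum(np.log(u * a)) - len(xs))
        if not a.any():
            v = len(xs) / (c @ xs)
            return float(np.sum(np.log(v * c)) - len(xs))
        return self.numeric_profile_strict(T, p_y, p_c)[2]

    def numeric_profile(self, T, p_y, p_c):
        """Numerically maximize the attribution loglik over the rates."""
        yule_counts, coal_prods = self.factors(T)

        def neg(v):
            ly, lc = np.exp(v)
            return -self.loglik(T, p_y, p_c, ly, lc)

        res = optimize.minimize(neg, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-13,
                                         "maxiter": 20000})
        ly, lc = np.exp(res.x)
        if not yule_counts:
            ly = math.nan
        if not coal_prods:
            lc = math.nan
        return ly, lc

    def profile_loglik(self, T, p_y, p_c) -> float:
        """Profiled loglik via the oracle's own closed forms."""
        rows = self.interval_counts(T)
        yule_counts, coal_prods = self.factors(T)
        D_y = sum(A**p_y * x for x, A, _ in rows if A > 0)
        D_c = sum(
            sum((n * (n - 1)) ** p_c for n in coal.values() if n > 1) * x
            for x, _, coal in rows
        )
        total = 0.0
        if yule_counts:
            ly = len(yule_counts) / D_y
            total += sum(math.log(ly * c**p_y) for c in yule_counts) - len(
                yule_counts
            )
        if coal_prods:
            lc = len(coal_prods) / D_c
            total += sum(math.log(lc * pr**p_c) for pr in coal_prods) - len(
                coal_prods
            )
        return total

    def _quick_profile(self, T, p_y, p_c) -> float:
        """Rate-profiled combined loglik via a quick 2-D quasi-Newton."""
        a, c, xs = self._ab_coefs(T, p_y, p_c)
        n = len(xs)
        if not c.any():
            u = n / (a @ xs)
            return float(np.sum(np.log(u * a)) - n)
        if not a.any():
            v = n / (c @ xs)
            return float(np.sum(np.log(v * c)) - n)
        At, Ct = a @ xs, c @ xs

        def neg(s):
            ly, lc = np.exp(s)
            b = ly * a + lc * c
            return -(np.sum(np.log(b)) - ly * At - lc * Ct)

        res = optimize.minimize(
            neg, [np.log(n / (2 * At)), np.log(n / (2 * Ct))],
            method="L-BFGS-B",
        )
        return -float(res.fun)

    def posterior_over_T(self, p_grid_size: int = 25) -> np.ndarray:
        """P(T) for T = 2..n_tips under the rate-profiled combined model,
        integrating the two exponents over their U(0, 2) priors by 2-D
        trapezoid quadrature."""
        ps = np.linspace(0.0, 2.0, p_grid_size)
        logpost = np.full(self.n_tips - 1, -np.inf)
        for T in range(2, self.n_tips + 1):
            M = np.array(
                [[self._quick_profile(T, py, pc) for pc in ps] for py in ps]
            )
            top = M.max()
            integ = np.trapezoid(
                np.trapezoid(np.exp(M - top), ps, axis=1), ps
            )
            logpost[T - 2] = top + np.log(integ)
        w = np.exp(logpost - logpost.max())
        return w / w.sum()
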