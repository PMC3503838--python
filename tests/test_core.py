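"""GMYC likelihood, profile rate MLEs, null model and threshold scan."""

import numpy as np
import pytest
from scipy import integrate, optimize

from gmyc import GMYCModel, GMYCParams, gmyc_loglik, ml_scan, null_loglik, profile_lambdas
from gmyc.core import coal_rate, combined_rate, interval_loglik, yule_rate
from gmyc.trees import threshold_counts


class TestRates:
    def test_yule_rate_values(self):
        assert yule_rate(1.0, 5, 1.0) == pytest.approx(5.0)
        assert yule_rate(2.0, 1, 0.0) == pytest.approx(2.0)

    def test_yule_rate_fold_change(self):
        # root-to-tip speciation-rate fold change n^p / n
        fold = yule_rate(1.0, 44, 1.9) / (1.0 * 44)
        assert fold == pytest.approx(30.1, abs=0.1)

    def test_coal_rate_values(self):
        assert coal_rate(1.0, 2, 1.0) == pytest.approx(2.0)
        assert coal_rate(1.0, 1, 1.0) == 0.0  # a lone lineage cannot coalesce
        assert coal_rate(0.5, 4, 1.0) == pytest.approx(6.0)

    @pytest.mark.parametrize("fn", [yule_rate, coal_rate])
    def test_rates_reject_bad_inputs(self, fn):
        with pytest.raises(ValueError):
            fn(1.0, 0, 1.0)
        with pytest.raises(ValueError):
            fn(-1.0, 2, 1.0)

    def test_combined_rate_mixture(self):
        params = GMYCParams(T=3, p_yule=1.0, p_coal=1.0,
                            lambda_yule=1.0, lambda_coal=2.0)
        b = combined_rate(1, [3], params)
        assert b == pytest.approx(1 + 2 * 6)

    def test_combined_rate_p_zero_counts_active_processes(self):
        params = GMYCParams(T=4, p_yule=0.0, p_coal=0.0,
                            lambda_yule=0.7, lambda_coal=0.3)
        # two active coalescent processes, one dormant (n = 1)
        b = combined_rate(2, [3, 2, 1], params)
        assert b == pytest.approx(0.7 + 2 * 0.3)

    def test_combined_rate_degenerate_warns(self):
        params = GMYCParams(T=2, lambda_yule=1.0, lambda_coal=1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            assert combined_rate(0, [1, 1], params) == 0.0

    def test_interval_loglik(self):
        assert interval_loglik(1.0, 1.0) == pytest.approx(-1.0)
        assert interval_loglik(1e-12, 1.0) == pytest.approx(0.0, abs=1e-9)
        with pytest.warns(UserWarning):
            assert interval_loglik(1.0, 0.0) == -np.inf

    def test_exponential_density_normalizes(self):
        for b in (0.3, 1.0, 7.5):
            val, _ = integrate.quad(
                lambda x: np.exp(interval_loglik(x, b)), 0, np.inf
            )
            assert val == pytest.approx(1.0, rel=1e-8)


class TestProfileLambdas:
    def test_pure_yule_toy(self, medium_sim_tree):
        # intervals (n=2, x=1), (n=3, x=0.5), two events, p = 1
        # lambda_hat = 2 / (2*1 + 3*0.5) = 2/3.5
        from gmyc.trees import UltrametricTree

        toy = UltrametricTree.from_newick("(((A:0.5,B:0.5):0.5,C:1):1,D:2);")
        tc = threshold_counts(toy, 4)  # all-Yule
        lam_y, lam_c = profile_lambdas(tc, p_yule=1.0)
        assert lam_y == pytest.approx(2 / 3.5, rel=1e-12)
        assert np.isnan(lam_c)

    def test_matches_numeric_maximization(self, small_sim_trees):
        from oracle_gmyc import OracleTree

        for tree in small_sim_trees:
            orc = OracleTree(tree.to_newick())
            for T in range(2, tree.n_tips + 1):
                for p_y, p_c in [(1.0, 1.0), (0.3, 1.7), (0.0, 0.0)]:
                    lam_y, lam_c = profile_lambdas(
                        threshold_counts(tree, T), p_yule=p_y, p_coal=p_c
                    )
                    ref_y, ref_c = orc.numeric_profile(T, p_y, p_c)
                    if np.isnan(lam_y):
                        assert np.isnan(ref_y)
                    else:
                        assert lam_y == pytest.approx(ref_y, rel=1e-6)
                    if np.isnan(lam_c):
                        assert np.isnan(ref_c)
                    else:
                        assert lam_c == pytest.approx(ref_c, rel=1e-6)

    def test_profile_is_local_maximum(self, medium_sim_tree):
        model = GMYCModel(medium_sim_tree)
        for T in (5, 10, 25):
            base, lam_y, lam_c = model.attribution_profile(T, 1.0, 1.0)
            for fac in (0.99, 1.01):
                perturbed = model.attribution_loglik(
                    GMYCParams(T, 1.0, 1.0, lam_y * fac, lam_c)
                )
                assert perturbed < base
                perturbed = model.attribution_loglik(
                    GMYCParams(T, 1.0, 1.0, lam_y, lam_c * fac)
                )
                assert perturbed < base


class TestLoglik:
    def test_matches_bruteforce_oracle_all_thresholds(self, small_sim_trees):
        from oracle_gmyc import OracleTree

        rng = np.random.default_rng(0)
        for tree in small_sim_trees:
            orc = OracleTree(tree.to_newick())
            model = GMYCModel(tree)
            for T in range(2, tree.n_tips + 1):
                p_y, p_c = rng.uniform(0, 2, size=2)
                ly, lc = rng.uniform(0.1, 3, size=2)
                ours = model.attribution_loglik(GMYCParams(T, p_y, p_c, ly, lc))
                ref = orc.loglik(T, p_y, p_c, ly, lc)
                assert ours == pytest.approx(ref, abs=1e-10)

    def test_combined_mode_matches_oracle(self, small_sim_trees):
        from oracle_gmyc import OracleTree

        for tree in small_sim_trees[:2]:
            orc = OracleTree(tree.to_newick())
            model = GMYCModel(tree)
            for T in range(2, tree.n_tips + 1):
                ours = model.combined_loglik(GMYCParams(T, 1.0, 1.0, 0.5, 2.0))
                ref = orc.loglik_strict(T, 1.0, 1.0, 0.5, 2.0)
                assert ours == pytest.approx(ref, abs=1e-10)

    def test_all_yule_threshold_equals_pure_yule_likelihood(self, medium_sim_tree):
        # independent pure-Yule computation: waiting time x_i with i+1
        # lineages has density lam*(i+1)^p * exp(-lam*(i+1)^p * x_i)
        from gmyc import ranked_branching_times

        t = ranked_branching_times(medium_sim_tree)
        x = -np.diff(t)
        lam, p = 0.8, 1.3
        counts = np.arange(2, 2 + len(x))
        rates = lam * counts.astype(float) ** p
        ref = float(np.sum(np.log(rates) - rates * x))
        ours = gmyc_loglik(
            medium_sim_tree,
            GMYCParams(medium_sim_tree.n_tips, p, 1.0, lam, 1.0),
        )
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_relabeling_tips_leaves_loglik_unchanged(self, balanced6):
        from gmyc.trees import UltrametricTree

        relabeled = UltrametricTree(
            balanced6.parent,
            balanced6.age,
            [f"x{i}" for i in range(balanced6.n_tips)],
        )
        pars = GMYCParams(3, 1.2, 0.8, 0.5, 1.5)
        assert gmyc_loglik(balanced6, pars) == pytest.approx(
            gmyc_loglik(relabeled, pars), rel=1e-15
        )

    def test_null_equals_forced_single_entity(self, medium_sim_tree):
        model = GMYCModel(medium_sim_tree)
        for p in (0.5, 1.0, 1.8):
            direct = null_loglik(medium_sim_tree, p=p)
            via_T1, _, _ = model.attribution_profile(1, 1.0, p)
            assert direct == pytest.approx(via_T1, rel=1e-12)

    def test_null_p_optimum_stays_in_bounds(self, medium_sim_tree):
        model = GMYCModel(medium_sim_tree)
        res = optimize.minimize_scalar(
            lambda p: -model.attribution_profile(1, 1.0, p)[0],
            bounds=(0.0, 2.0), method="bounded",
        )
        assert 0.0 <= res.x <= 2.0


class TestCombinedProfile:
    def test_newton_rates_match_numeric_maximization(self, small_sim_trees):
        from oracle_gmyc import OracleTree

        for tree in small_sim_trees[:2]:
            orc = OracleTree(tree.to_newick())
            model = GMYCModel(tree)
            for T in range(2, tree.n_tips + 1):
                for p_y, p_c in [(1.0, 1.0), (0.4, 1.6)]:
                    logL, ly, lc = model.combined_profile(T, p_y, p_c)
                    ref_y, ref_c, ref_logL = orc.numeric_profile_strict(
                        T, p_y, p_c
                    )
                    assert logL == pytest.approx(ref_logL, abs=1e-7)
                    if np.isfinite(ly) and np.isfinite(ref_y):
                        assert ly == pytest.approx(ref_y, rel=1e-4)
                    if np.isfinite(lc) and np.isfinite(ref_c):
                        assert lc == pytest.approx(ref_c, rel=1e-4)

    def test_profiled_rates_are_a_local_maximum(self, medium_sim_tree):
        model = GMYCModel(medium_sim_tree)
        for T in (5, 10, 25):
            base, ly, lc = model.combined_profile(T, 1.0, 1.0)
            for fac in (0.98, 1.02):
                assert model.combined_loglik(
                    GMYCParams(T, 1.0, 1.0, ly * fac, lc)
                ) < base
                assert model.combined_loglik(
                    GMYCParams(T, 1.0, 1.0, ly, lc * fac)
                ) < base

    def test_single_process_forms_coincide(self, medium_sim_tree):
        """Null (T=1) and all-Yule (T=n): combined == attribution exactly."""
        model = GMYCModel(medium_sim_tree)
        for T in (1, medium_sim_tree.n_tips):
            for p in (0.5, 1.0, 1.7):
                la, _, _ = model.attribution_profile(T, p, p)
                lb, _, _ = model.combined_profile(T, p, p)
                assert la == pytest.approx(lb, rel=1e-10)


class TestKingmanLimit:
    def test_within_cluster_matches_kingman_density(self):
        """p_c = 1, lam_c = 1/(2N): the coalescent part is Kingman.

        Two clades at T = 2; with the Yule part's survival subtracted the
        remaining terms equal the product of Kingman inter-event densities
        (rate n(n-1)/2 * 1/N per N-generation unit for diploids; the segment
        to the present and the root's own waiting time are censored).
        """
        from gmyc.trees import UltrametricTree

        nwk = "(((a:1,b:1):2,c:3):7,((d:2,e:2):1.5,f:3.5):6.5);"
        tree = UltrametricTree.from_newick(nwk)
        N = 1.0
        lam_c = 1.0 / (2 * N)
        lam_y = 0.37
        model = GMYCModel(tree)
        # the event-attributed form is the one that factorizes into
        # per-process densities, so it is the Kingman comparison target
        ours = model.attribution_loglik(GMYCParams(2, 1.0, 1.0, lam_y, lam_c))

        # Kingman product over both clusters, chopped at every event age
        ages = sorted(
            [3.0, 1.0, 3.5, 2.0], reverse=True
        )  # cluster MRCAs and internal events
        t = [10.0] + ages  # all event ages, root first
        x = -np.diff(t)
        # lineage counts per interval for each cluster (by hand):
        # intervals: [3.5,10] counts a:1 d:1; [3,3.5] a1 d2; [2,3] a2 d2;
        # [1,2] a2 d3
        cl_a = [0, 0, 2, 2]  # 1-lineage stems carry no coalescent hazard
        cl_d = [0, 2, 2, 3]
        surv = 0.0
        for xi, na, nd in zip(x, cl_a, cl_d):
            b = lam_c * (na * (na - 1)) + lam_c * (nd * (nd - 1))
            surv += -b * xi
        # factor for each observed coalescent event (rank 2..m-1): the three
        # cluster MRCAs at ages 3.5, 3, 2 (the youngest event, age 1, has no
        # observed waiting segment); counts just below are 2, 2, 3
        factors = sum(np.log(lam_c * n * (n - 1)) for n in (2.0, 2.0, 3.0))
        # Yule survival: crossing branches count as interspecific until
        # their cluster's own MRCA
        A = [2, 1, 0, 0]  # both stems above 3.5; a-side stem until age 3
        yule_surv = sum(-lam_y * a * xi for a, xi in zip(A, x))
        ref = surv + factors + yule_surv
        assert ours == pytest.approx(ref, rel=1e-12)


class TestMLScan:
    def test_akaike_weights_sum_to_one(self, medium_sim_tree):
        res = ml_scan(medium_sim_tree)
        assert res.akaike_weights.sum() == pytest.approx(1.0)
        assert res.best_T == int(
            res.table.loc[res.table.loglik.idxmax(), "T"]
        )

    def test_scan_covers_all_thresholds(self, medium_sim_tree):
        res = ml_scan(medium_sim_tree)
        assert len(res.table) + len(res.excluded) == medium_sim_tree.n_tips - 1
        assert res.lr_stat >= 0 or res.lr_pvalue >= 0

    def test_recovers_species_count_on_deep_tree(self, deep_sim_tree):
        """At 160 N depth the ML threshold should sit near the true 50."""
        res = ml_scan(deep_sim_tree)
        assert 40 <= res.best_T <= 62
        assert res.lr_pvalue < 0.01

    def test_report_mentions_confidence_interval(self, medium_sim_tree):
        res = ml_scan(medium_sim_tree)
        text = res.report()
        assert "species with a support interval" in text
        cs = res.confidence_set()
        assert res.best_T in cs
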