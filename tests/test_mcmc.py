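import numpy as np
import pytest
from scipy import stats as ss

from morphclock import mcmc
from morphclock.io_formats import RunConfig
from morphclock.treedata import Node, TimeTree


def prior_cfg(**kw):
    base = dict(
        clock_model="igr", sampling_strategy="fossiltip",
        root_prior_kind="offset_exponential", root_prior_params=(70.0, 100.0),
        n_generations=4000, n_runs=1, sample_interval=20, seed=13, burn_in=0.2,
    )
    base.update(kw)
    return RunConfig(**base)


FIXED_TREE_WEIGHTS = {
    "node_age": 0, "root_age": 0, "tree_scale": 0, "tip_age": 0,
    "narrow_exchange": 0, "spr": 0, "sa_add": 0, "sa_delete": 0,
    "clock_rescale": 4.0, "base_rate": 3.0, "branch_redraw": 2.0,
    "rate_age_tradeoff": 0, "igr_var_rescale": 2.0,
}


class TestPriorSampling:
    def test_clock_marginals_match_priors_on_fixed_tree(self, six_taxon_data):
        """With the likelihood off and the tree held fixed, the base clock
        rate, clock variance and ACRV shape are conditionally independent of
        the tree, so their marginals are exactly their priors."""
        matrix, cal = six_taxon_data
        cfg = prior_cfg(n_generations=250_000, sample_interval=50,
                        fix_topology=True, move_weights=FIXED_TREE_WEIGHTS)
        res = mcmc.run_mcmc(cfg, matrix, cal, likelihood_power=0.0)
        samp = res["post_burnin"][0]
        c = np.array([s.scalars["clock_rate_all"] for s in samp])
        v = np.array([s.scalars["clock_var_all"] for s in samp])
        a = np.array([s.scalars["acrv_shape_all"] for s in samp])
        ks_c = ss.kstest(c, lambda x: ss.lognorm.cdf(x, s=1.0202, scale=0.02))
        ks_v = ss.kstest(v, lambda x: 1 - np.exp(-10.0 * x))
        ks_a = ss.kstest(a, lambda x: 1 - np.exp(-x))
        assert ks_c.statistic < 0.08
        assert ks_v.statistic < 0.08
        assert ks_a.statistic < 0.08

    def test_prior_runs_agree_across_seeds(self, six_taxon_data):
        """Two independent prior-only chains sample the same root-age
        distribution (two-sample KS self-consistency)."""
        matrix, cal = six_taxon_data
        cfg = prior_cfg(sampling_strategy="random", n_generations=200_000,
                        sample_interval=150, n_runs=2, seed=3,
                        move_weights={"branch_redraw": 2.0, "tree_scale": 2.0,
                                      "sa_add": 2.0, "sa_delete": 2.0})
        res = mcmc.run_mcmc(cfg, matrix, cal, likelihood_power=0.0)
        roots = [np.array([s.scalars["root_age"] for s in run])
                 for run in res["post_burnin"]]
        ks = ss.ks_2samp(roots[0], roots[1])
        assert ks.statistic < 0.12
        # both runs visit sampled-ancestor and tip configurations
        nsa = np.array([s.scalars["n_sa"] for run in res["post_burnin"]
                        for s in run])
        assert 0 < nsa.mean() < 2


class TestRunMcmc:
    def test_reproducible_with_same_seed(self, six_taxon_data):
        matrix, cal = six_taxon_data
        out = []
        for _ in range(2):
            res = mcmc.run_mcmc(prior_cfg(n_generations=1500), matrix, cal)
            out.append([(s.scalars["lnL"], s.scalars["root_age"],
                         s.tree.to_newick()) for s in res["runs"][0]["samples"]])
        assert out[0] == out[1]

    def test_nosa_strategy_never_samples_ancestors(self, six_taxon_data):
        matrix, cal = six_taxon_data
        cfg = prior_cfg(sampling_strategy="nosa_diversity", x_cut=10.0,
                        n_generations=3000)
        res = mcmc.run_mcmc(cfg, matrix, cal)
        for s in res["runs"][0]["samples"]:
            assert s.scalars["n_sa"] == 0

    def test_random_strategy_visits_sampled_ancestors(self, six_taxon_data):
        matrix, cal = six_taxon_data
        cfg = prior_cfg(sampling_strategy="random", n_generations=4000)
        res = mcmc.run_mcmc(cfg, matrix, cal)
        nsa = [s.scalars["n_sa"] for s in res["runs"][0]["samples"]]
        assert max(nsa) >= 1

    def test_fixed_topology_and_rate_mode(self, six_taxon_data):
        matrix, cal = six_taxon_data
        cfg = prior_cfg(fix_topology=True, fix_clock_rate=True,
                        n_generations=2000)
        res = mcmc.run_mcmc(cfg, matrix, cal)
        samples = res["runs"][0]["samples"]
        topologies = {frozenset(s.tree.clades().values()) -
                      {c for c in s.tree.clades().values() if len(c) == 1}
                      for s in samples}
        rates = {s.scalars["clock_rate_all"] for s in samples}
        ages = {round(s.scalars["root_age"], 6) for s in samples}
        assert len({frozenset(t) for t in topologies}) == 1
        assert len(rates) == 1
        assert len(ages) > 1  # ages still move

    def test_partitioned_run_produces_per_partition_traces(self, six_taxon_data):
        matrix, cal = six_taxon_data
        matrix.partition_map = ["p1", "p2"]
        cfg = prior_cfg(n_generations=1500)
        res = mcmc.run_mcmc(cfg, matrix, cal)
        s = res["runs"][0]["samples"][-1]
        assert "clock_rate_p1" in s.scalars and "clock_rate_p2" in s.scalars
        matrix.partition_map = None


class TestDiagnostics:
    def test_asdsf_identical_runs_is_zero(self, four_taxon_tree):
        trees = [four_taxon_tree.copy() for _ in range(5)]
        assert mcmc.compute_asdsf([trees, [t.copy() for t in trees]]) == 0.0

    def test_asdsf_hand_computed_conflict(self):
        def tree_of(pair):
            root = Node(2.0)
            inner = root.add_child(Node(1.0))
            for t in pair[0]:
                inner.add_child(Node(0.0, t))
            for t in pair[1]:
                root.add_child(Node(0.0, t))
            return TimeTree(root)

        run1 = [tree_of((("A", "B"), ("C", "D")))] * 4
        run2 = [tree_of((("A", "C"), ("B", "D")))] * 4
        # two conflicting splits with frequencies {1,0} and {0,1}:
        # population sd 0.5 each, mean 0.5
        assert mcmc.compute_asdsf([run1, run2]) == pytest.approx(0.5)

    def test_asdsf_min_freq_filter(self):
        def tree_of(pair):
            root = Node(2.0)
            inner = root.add_child(Node(1.0))
            for t in pair[0]:
                inner.add_child(Node(0.0, t))
            for t in pair[1]:
                root.add_child(Node(0.0, t))
            return TimeTree(root)

        common = tree_of((("A", "B"), ("C", "D")))
        rare = tree_of((("A", "C"), ("B", "D")))
        run1 = [common] * 99 + [rare]
        run2 = [common] * 100
        # the rare split (freq 0.01) falls below the threshold
        val = mcmc.compute_asdsf([run1, run2], min_freq=0.1)
        assert val == pytest.approx(0.005, abs=1e-12)

    def test_asdsf_single_run_rejected(self, four_taxon_tree):
        with pytest.raises(ValueError):
            mcmc.compute_asdsf([[four_taxon_tree]])

    def test_psrf_identical_traces(self, rng):
        t = rng.standard_normal(500)
        assert mcmc.compute_psrf([t, t.copy()]) == pytest.approx(1.0, abs=0.01)

    def test_psrf_diverged_traces(self, rng):
        a = rng.standard_normal(500)
        b = rng.standard_normal(500) + 10.0
        assert mcmc.compute_psrf([a, b]) > 3.0

    def test_ess_iid_normal(self):
        x = np.random.default_rng(8).standard_normal(1000)
        assert 700 <= mcmc.compute_ess(x) <= 1300

    def test_ess_ar1_closed_form(self):
        rng = np.random.default_rng(9)
        phi = 0.9
        n = 20_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.standard_normal()
        expected = n * (1 - phi) / (1 + phi)
        got = mcmc.compute_ess(x)
        assert expected / 2 <= got <= expected * 2

    def test_ess_constant_trace_reports_n(self):
        assert mcmc.compute_ess(np.full(100, 2.0)) == 100.0

    def test_compute_psrf_ess_bundle(self, rng):
        traces = {"p": [rng.standard_normal(300), rng.standard_normal(300)]}
        out = mcmc.compute_psrf_ess(traces)
        assert out["p"]["psrf"] == pytest.approx(1.0, abs=0.05)
        assert out["p"]["ess"] <= 600
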