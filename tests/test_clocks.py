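import math

import numpy as np
import pytest

from morphclock import clocks
from morphclock.treedata import random_calibrated_tree


class TestClockPriorDerivation:
    def test_tree_height_ratio(self):
        out = clocks.derive_clock_prior(5.3456, 267.1)
        assert out["mean"] == pytest.approx(0.02, abs=5e-5)

    def test_lognormal_parameters(self):
        out = clocks.derive_clock_prior(5.3456, 267.1)
        assert out["lognormal_logmean"] == pytest.approx(math.log(5.3456 / 267.1),
                                                         abs=1e-12)
        # reported at two decimals: ln(0.02) and exp(0.02)
        assert round(math.log(round(out["mean"], 2)), 4) == -3.9120
        assert round(out["lognormal_logsd"], 4) == 1.0202

    def test_gamma_parameters(self):
        out = clocks.derive_clock_prior(5.3456, 267.1, gamma_sd=0.5)
        assert out["gamma"].mean == pytest.approx(0.02, abs=5e-5)
        assert out["gamma"].sd == 0.5

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clocks.derive_clock_prior(0.0, 267.1)
        with pytest.raises(ValueError):
            clocks.derive_clock_prior(5.0, -1.0)


@pytest.fixture
def small_tree(rng):
    return random_calibrated_tree({t: 0.0 for t in "ABCDEF"}, 50.0, rng)


class TestIgrClock:
    def test_strict_limit(self, small_tree, rng):
        state = clocks.ClockState("igr", base_rate=0.02, variance=1e-12)
        eff, lp = clocks.igr_effective_lengths(small_tree, state, rng)
        for node, v in eff.items():
            assert v == pytest.approx(0.02 * small_tree.duration(node), abs=1e-6)

    def test_stated_moments(self):
        # Gamma(mean = c t = 0.2, variance = c t nu = 0.004)
        c, t, nu = 0.02, 10.0, 0.02
        rng = np.random.default_rng(0)
        draws = np.array([clocks.sample_igr_branch(t, c, nu, rng)
                          for _ in range(100_000)])
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - 0.2) < 3 * se
        assert draws.var() == pytest.approx(0.004, rel=0.05)

    def test_density_matches_sampler(self, rng):
        """Monte-Carlo mean of the log-prior gradient sanity: histogram of
        samples agrees with the analytic density by moment matching."""
        c, t, nu = 0.05, 8.0, 0.1
        draws = np.array([clocks.sample_igr_branch(t, c, nu, rng)
                          for _ in range(50_000)])
        # analytic mean/var of Gamma(shape ct/nu, scale nu)
        assert draws.mean() == pytest.approx(c * t, rel=0.02)
        assert draws.var() == pytest.approx(c * t * nu, rel=0.05)
        lp = clocks.igr_branch_log_prior(t, c, nu, c * t)
        assert np.isfinite(lp)

    def test_zero_duration_with_positive_length_is_minus_inf(self, small_tree, rng):
        state = clocks.ClockState("igr", base_rate=0.02, variance=0.05)
        clocks.igr_effective_lengths(small_tree, state, rng)
        # pin one branch to zero duration, keep its positive value
        child = small_tree.root.children[0]
        child.age = small_tree.root.age
        for g in child.children:
            g.age = min(g.age, child.age)
        state.branch_values[child] = 0.5
        _, lp = clocks.igr_effective_lengths(small_tree, state, rng)
        assert lp == -np.inf


class TestTk02Clock:
    def test_strict_limit(self, small_tree, rng):
        state = clocks.ClockState("tk02", base_rate=0.02, variance=0.0)
        eff, lp = clocks.tk02_effective_lengths(small_tree, state, rng)
        for node, v in eff.items():
            assert v == pytest.approx(0.02 * small_tree.duration(node), abs=1e-9)

    def test_mean_preservation(self, rng):
        r_parent, nu, t = 0.03, 0.2, 7.0
        draws = np.array([clocks.sample_tk02_rate(r_parent, nu, t, rng)
                          for _ in range(100_000)])
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - r_parent) < 3 * se

    def test_log_increment_variance(self, rng):
        r_parent, nu, t = 0.02, 0.05, 12.0
        draws = np.array([clocks.sample_tk02_rate(r_parent, nu, t, rng)
                          for _ in range(100_000)])
        lv = np.log(draws).var()
        assert lv == pytest.approx(nu * t, rel=0.03)

    def test_branch_length_is_midpoint_rule(self, small_tree, rng):
        state = clocks.ClockState("tk02", base_rate=0.02, variance=0.1)
        eff, _ = clocks.tk02_effective_lengths(small_tree, state, rng)
        rates = {small_tree.root: 0.02}
        for node in small_tree.preorder():
            if node.parent is None:
                continue
            rates[node] = state.branch_values[node]
            t = small_tree.duration(node)
            assert eff[node] == pytest.approx(
                t * 0.5 * (rates[node.parent] + rates[node]))


class TestScalingAndReduction:
    @pytest.mark.parametrize("model", ["strict", "igr", "tk02"])
    def test_lengths_nonnegative_and_linear_in_c(self, model, small_tree, rng):
        state = clocks.ClockState(model, base_rate=0.02,
                                  variance=0.0 if model == "strict" else 0.05)
        eff1, _ = clocks.effective_lengths(small_tree, state, rng)
        assert all(v >= 0 for v in eff1.values())
        if model == "strict":
            state2 = clocks.ClockState(model, base_rate=0.04)
            eff2, _ = clocks.effective_lengths(small_tree, state2, rng)
            for n in eff1:
                assert eff2[n] == pytest.approx(2 * eff1[n])

    def test_both_models_reduce_to_strict(self, small_tree, rng):
        strict = clocks.strict_effective_lengths(small_tree, 0.02)
        for model in ("igr", "tk02"):
            state = clocks.ClockState(model, base_rate=0.02, variance=1e-14)
            eff, _ = clocks.effective_lengths(small_tree, state, rng)
            for n, v in strict.items():
                assert eff[n] == pytest.approx(v, abs=1e-6)


class TestPartitionClocks:
    def test_partition_size_bound(self):
        warnings = clocks.check_partition_sizes(
            35, {"skull": 47, "mandible": 44, "postcranial": 38})
        # 2n-1 = 69 at n = 35: all three partitions are under-sized
        assert len(warnings) == 3
        assert "69" in warnings[0]

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            clocks.check_partition_sizes(10, {"skull": 0})

    def test_identical_states_reduce_to_single_clock(self, small_tree, rng):
        base = clocks.ClockState("strict", base_rate=0.02)
        scheme = clocks.PartitionClockScheme({
            "a": clocks.ClockState("strict", base_rate=0.02),
            "b": clocks.ClockState("strict", base_rate=0.02),
        })
        per, lp = clocks.apply_partition_clocks(small_tree, scheme, rng)
        single, _ = clocks.effective_lengths(small_tree, base, rng)
        assert per["a"] == single
        assert per["b"] == single
        assert lp == 0.0
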