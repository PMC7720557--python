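import math

import numpy as np
import pytest

from morphclock import fbd
from morphclock.io_formats import Calibration, CalibrationTable
from morphclock.treedata import Node, TimeTree


def bd_p0(t, lam, mu):
    return 1.0 - (lam - mu) / (lam - mu * math.exp(-(lam - mu) * t))


def bd_p1(t, lam, mu):
    e = math.exp(-(lam - mu) * t)
    return (lam - mu) ** 2 * e / (lam - mu * e) ** 2


def bd_log_density(tree, lam, mu):
    """Closed-form birth-death density given the root age, conditioned on
    both root lineages surviving (independent textbook oracle)."""
    internal = [n.age for n in tree.internals()]
    root = tree.root.age
    others = [a for a in internal if a != root] or []
    n_tips = len(tree.leaves())
    logf = (n_tips - 2) * math.log(lam)
    logf += 2 * math.log(bd_p1(root, lam, mu))
    logf += sum(math.log(bd_p1(a, lam, mu)) for a in others)
    logf -= 2 * math.log(1.0 - bd_p0(root, lam, mu))
    return logf


@pytest.fixture
def ultrametric_tree():
    root = Node(10.0)
    x = root.add_child(Node(6.0))
    root.add_child(Node(0.0, "D"))
    y = x.add_child(Node(3.0))
    x.add_child(Node(0.0, "C"))
    y.add_child(Node(0.0, "A"))
    y.add_child(Node(0.0, "B"))
    return TimeTree(root)


@pytest.fixture
def fossil_tree():
    """Root 20: one fossil tip at 8, one sampled ancestor at 5."""
    root = Node(20.0)
    left = root.add_child(Node(12.0))
    right = root.add_child(Node(0.0, "C"))
    left.add_child(Node(8.0, "Fossil"))
    sa_host = left.add_child(Node(5.0))
    sa_host.add_child(Node(0.0, "A"))
    sa_host.add_child(Node(5.0, "Anc"))  # zero-duration: sampled ancestor
    return TimeTree(root)


class TestCanonicalTransform:
    def test_worked_triple(self):
        assert fbd.to_canonical(0.1, 0.5, 0.5) == pytest.approx((0.2, 0.1, 0.1))

    def test_pure_birth_corner(self):
        assert fbd.to_canonical(0.3, 0.0, 0.0) == pytest.approx((0.3, 0.0, 0.0))

    def test_round_trip(self, rng):
        for _ in range(1000):
            d = rng.uniform(1e-3, 1.0)
            r = rng.uniform(0.0, 0.999)
            s = rng.uniform(0.0, 0.999)
            back = fbd.from_canonical(*fbd.to_canonical(d, r, s))
            assert np.allclose(back, (d, r, s), atol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fbd.to_canonical(0.1, 1.0, 0.5)
        with pytest.raises(ValueError):
            fbd.to_canonical(-0.1, 0.5, 0.5)


class TestConstantDensityOracles:
    def test_reduces_to_birth_death(self, ultrametric_tree):
        lam, mu = 0.3, 0.1
        d, r, s = fbd.from_canonical(lam, mu, 0.0)
        params = fbd.FBDParams(d, r, s, rho=1.0)
        got = fbd.fbd_log_density(ultrametric_tree, params,
                                  fbd.SamplingStrategy("fossiltip"))
        assert got == pytest.approx(bd_log_density(ultrametric_tree, lam, mu),
                                    abs=1e-9)

    def test_reduces_to_yule(self, ultrametric_tree):
        lam = 0.4
        params = fbd.FBDParams(lam, 0.0, 0.0, rho=1.0)
        got = fbd.fbd_log_density(ultrametric_tree, params,
                                  fbd.SamplingStrategy("fossiltip"))
        # Yule given root age: lambda^(n-2) exp(-lambda * tree length)
        length = 2 * 10.0 + 6.0 + 3.0
        assert got == pytest.approx(2 * math.log(lam) - lam * length, abs=1e-9)

    def test_finite_for_fossil_trees(self, fossil_tree):
        params = fbd.FBDParams(0.05, 0.5, 0.4, rho=1.0)
        for strat in ("random",):
            v = fbd.fbd_log_density(fossil_tree, params,
                                    fbd.SamplingStrategy(strat))
            assert np.isfinite(v)

    def test_sampled_ancestor_forbidden_under_fossiltip(self, fossil_tree):
        params = fbd.FBDParams(0.05, 0.5, 0.4, rho=1.0)
        assert fbd.fbd_log_density(fossil_tree, params,
                                   fbd.SamplingStrategy("fossiltip")) == -np.inf

    def test_tip_relabeling_invariance(self, fossil_tree):
        params = fbd.FBDParams(0.05, 0.5, 0.4, rho=1.0)
        a = fbd.fbd_log_density(fossil_tree, params, fbd.SamplingStrategy("random"))
        relabeled = fossil_tree.copy()
        for leaf in relabeled.leaves():
            leaf.taxon = leaf.taxon + "_x"
        b = fbd.fbd_log_density(relabeled, params, fbd.SamplingStrategy("random"))
        assert a == b

    def test_fossil_event_term_monotone_in_psi(self, fossil_tree):
        """More fossil sampling raises the per-event psi contribution."""
        vals = []
        for s in (0.1, 0.3, 0.6):
            params = fbd.FBDParams(0.05, 0.5, s, rho=1.0)
            _, _, psi = params.canonical()
            vals.append(math.log(psi))
        assert vals[0] < vals[1] < vals[2]


class TestSkyline:
    def test_degenerates_to_constant(self, fossil_tree):
        params = fbd.FBDParams(0.05, 0.5, 0.4, rho=1.0)
        grid = fbd.SkylineGrid((10.0, 4.0), [params, params, params], "sdr")
        strat = fbd.SamplingStrategy("random")
        a = fbd.skyline_fbd_log_density(fossil_tree, grid, strat)
        b = fbd.fbd_log_density(fossil_tree, params, strat)
        assert a == pytest.approx(b, abs=1e-9)

    def test_s_mask_shares_d_and_r(self):
        p1 = fbd.FBDParams(0.05, 0.5, 0.4)
        p2 = fbd.FBDParams(0.05, 0.5, 0.1)
        grid = fbd.SkylineGrid((145.0,), [p1, p2], "s")
        assert grid.n_free_parameters() == 2 + 2  # l + 2 with l = 2 slices
        with pytest.raises(ValueError):
            fbd.SkylineGrid((145.0,), [p1, fbd.FBDParams(0.08, 0.5, 0.1)], "s")

    def test_three_slice_grid_and_free_parameters(self):
        p = fbd.FBDParams(0.05, 0.5, 0.4)
        grid = fbd.SkylineGrid((145.0, 66.0), [p, p, p], "sdr")
        assert grid.n_free_parameters() == 9  # 3l with l = 3 slices
        assert grid.slice_index(200.0) == 0
        assert grid.slice_index(145.0) == 0  # boundary closed on the old side
        assert grid.slice_index(100.0) == 1
        assert grid.slice_index(66.0) == 1
        assert grid.slice_index(10.0) == 2

    def test_shift_older_than_root_rejected(self, fossil_tree):
        p = fbd.FBDParams(0.05, 0.5, 0.4)
        grid = fbd.SkylineGrid((50.0,), [p, p], "sdr")
        with pytest.raises(ValueError):
            fbd.skyline_fbd_log_density(fossil_tree, grid,
                                        fbd.SamplingStrategy("random"))

    def test_diversified_sampling_constraints(self, fossil_tree):
        p = fbd.FBDParams(0.05, 0.5, 0.4)
        grid = fbd.SkylineGrid((), [p], "sdr", x_cut=66.0)
        # fossil at 8 Ma is younger than x_cut = 66 -> impossible
        strat = fbd.SamplingStrategy("diversity", x_cut=66.0)
        assert fbd.skyline_fbd_log_density(fossil_tree, grid, strat) == -np.inf
        # with a tiny cutoff the density is finite
        strat2 = fbd.SamplingStrategy("diversity", x_cut=1.0)
        grid2 = fbd.SkylineGrid((), [p], "sdr", x_cut=1.0)
        assert np.isfinite(fbd.skyline_fbd_log_density(fossil_tree, grid2, strat2))


class TestRootAndTipPriors:
    def test_offset_exponential_shape(self):
        cal = fbd.RootCalibration("offset_exponential", (247.2, 287.0))
        assert cal.log_density(240.0) == -np.inf
        dens = [cal.log_density(a) for a in (247.2, 260.0, 300.0)]
        assert dens[0] > dens[1] > dens[2]

    def test_truncated_normal_hard_bounds(self):
        cal = fbd.RootCalibration("truncated_normal", (270.0, 15.0, 247.2, 298.9))
        assert cal.log_density(300.0) == -np.inf  # above the earliest Permian
        assert cal.log_density(240.0) == -np.inf
        assert np.isfinite(cal.log_density(270.0))

    def test_tip_age_uniform_support(self, fossil_tree):
        root_cal = fbd.RootCalibration("offset_exponential", (15.0, 30.0))
        cal = CalibrationTable({
            "A": Calibration(0, 0), "C": Calibration(0, 0),
            "Fossil": Calibration(6.0, 9.0), "Anc": Calibration(4.0, 6.0),
        })
        lp = fbd.root_and_tip_log_priors(fossil_tree, root_cal, cal)
        assert np.isfinite(lp)
        # move the fossil outside its range
        fossil_tree.find_leaf("Fossil").age = 5.0
        assert fbd.root_and_tip_log_priors(fossil_tree, root_cal, cal) == -np.inf

    def test_extant_tip_with_nonzero_age_rejected(self, ultrametric_tree):
        root_cal = fbd.RootCalibration("offset_exponential", (8.0, 20.0))
        cal = CalibrationTable({t: Calibration(0, 0) for t in "ABCD"})
        ultrametric_tree.find_leaf("A").age = 1.0
        with pytest.raises(ValueError):
            fbd.root_and_tip_log_priors(ultrametric_tree, root_cal, cal)
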