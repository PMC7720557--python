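import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from morphclock import likelihood as lk
from morphclock.io_formats import CharacterMatrix
from morphclock.treedata import Node, TimeTree, random_calibrated_tree


def mk_spec(**kw):
    return lk.MkModelSpec(**kw)


class TestTransitionProbability:
    def test_zero_length_is_identity(self):
        assert np.allclose(lk.mk_transition_probability(2, 0.0), np.eye(2))

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_matches_matrix_exponential(self, k):
        # rate matrix with unit expected substitution rate
        Q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(Q, -1.0)
        for nu in (0.1, 0.7, 2.5):
            assert np.allclose(lk.mk_transition_probability(k, nu), expm(Q * nu),
                               atol=1e-12)

    def test_two_state_worked_value(self):
        P = lk.mk_transition_probability(2, 0.1)
        assert P[0, 0] == pytest.approx(0.90937, abs=1e-5)
        assert P[0, 1] == pytest.approx(0.09063, abs=1e-5)

    def test_stationarity_limit_and_row_sums(self):
        for k in (2, 4):
            P = lk.mk_transition_probability(k, 60.0)
            assert np.allclose(P, 1.0 / k, atol=1e-9)
            assert np.allclose(lk.mk_transition_probability(k, 0.33).sum(axis=1), 1.0)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            lk.mk_transition_probability(2, -0.1)


class TestAcrvDiscretization:
    def test_single_category(self):
        cats = lk.discretize_acrv(mk_spec(n_rate_categories=1))
        assert cats == [(1.0, 1.0)]

    def test_degenerate_gamma(self):
        cats = lk.discretize_acrv(mk_spec(acrv_kind="gamma", acrv_shape=1e6,
                                          n_rate_categories=4))
        assert all(abs(r - 1.0) < 1e-2 for r, _ in cats)

    @pytest.mark.parametrize("kind,alpha", [("gamma", 0.5), ("gamma", 2.0),
                                            ("lognormal", 0.5), ("lognormal", 1.2)])
    def test_category_means_against_quadrature(self, kind, alpha):
        """Category rates equal numerical quadrature of the mean-1 density
        over equal-probability slices."""
        from scipy import integrate, stats
        n = 4
        cats = lk.discretize_acrv(mk_spec(acrv_kind=kind, acrv_shape=alpha,
                                          n_rate_categories=n))
        rates = [r for r, _ in cats]
        assert all(r2 > r1 for r1, r2 in zip(rates, rates[1:]))
        assert sum(r * w for r, w in cats) == pytest.approx(1.0, abs=1e-9)
        if kind == "gamma":
            dist = stats.gamma(a=alpha, scale=1.0 / alpha)
        else:
            dist = stats.lognorm(s=alpha, scale=math.exp(-alpha ** 2 / 2))
        qs = dist.ppf(np.arange(n + 1) / n)
        for i, (r, _) in enumerate(cats):
            lo, hi = qs[i], qs[i + 1]
            num, _ = integrate.quad(lambda x: x * dist.pdf(x), lo,
                                    min(hi, dist.ppf(1 - 1e-12)))
            assert r == pytest.approx(num * n, rel=1e-5)

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            lk.discretize_acrv(mk_spec(acrv_shape=-1.0))


class TestAsymmetricFrequencies:
    def test_beta_quantile_midpoints_k2(self):
        from scipy import stats
        cats = lk.asymmetric_frequency_mixture(2, 1.0, 4)
        expected = stats.beta.ppf([0.125, 0.375, 0.625, 0.875], 1, 1)
        got = [f[0] for f, _ in cats]
        assert np.allclose(got, expected)
        for f, _ in cats:
            assert f.sum() == pytest.approx(1.0)
        # symmetric about 0.5
        assert np.allclose(sorted(got), sorted(1 - np.array(got)))

    def test_high_concentration_reduces_to_uniform(self):
        for k in (2, 3):
            cats = lk.asymmetric_frequency_mixture(k, 1e7, 4)
            for f, _ in cats:
                assert np.allclose(f, 1.0 / k, atol=1e-3)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_mean_frequency_is_uniform(self, k):
        cats = lk.asymmetric_frequency_mixture(k, 0.7, 5)
        mean = sum(w * f for f, w in cats)
        total_w = sum(w for _, w in cats)
        assert total_w == pytest.approx(1.0)
        assert np.allclose(mean, 1.0 / k, atol=1e-6)


def _brute_force_loglik(tree, eff, matrix, spec, ascertainment):
    """Exhaustive sum over interior-node states (independent oracle)."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    total = 0.0
    for j in range(matrix.n_characters):
        k = matrix.char_state_counts[j]
        rate_cats = lk.discretize_acrv(spec)
        if spec.freq_model == "asymmetric":
            freq_cats = lk.asymmetric_frequency_mixture(k, spec.alpha_dir,
                                                        spec.n_freq_categories)
        else:
            freq_cats = [(np.full(k, 1.0 / k), 1.0)]

        def pattern_prob(state_sets):
            tot = 0.0
            for freqs, fw in freq_cats:
                for rate, rw in rate_cats:
                    s = 0.0
                    for assign in itertools.product(range(k), repeat=len(internals)):
                        amap = dict(zip(internals, assign))
                        p = freqs[amap[tree.root]]
                        for n in nodes:
                            if n.parent is None:
                                continue
                            P = lk.mk_transition_probability(k, rate * eff[n], freqs)
                            if n.is_leaf:
                                p *= sum(P[amap[n.parent], s2]
                                         for s2 in state_sets[n.taxon])
                            else:
                                p *= P[amap[n.parent], amap[n]]
                        s += p
                    tot += fw * rw * s
            return tot

        sets = {}
        for i, t in enumerate(matrix.taxon_names):
            c = matrix.cells[i][j]
            if c is None:
                sets[t] = list(range(k))
            elif isinstance(c, frozenset):
                sets[t] = sorted(c)
            else:
                sets[t] = [c]
        p = pattern_prob(sets)
        if ascertainment:
            pc = sum(pattern_prob({t: [s] for t in matrix.taxon_names})
                     for s in range(k))
            p = p / (1.0 - pc)
        total += math.log(p)
    return total


class TestMatrixLogLikelihood:
    def test_two_taxon_uncorrected_value(self, two_taxon_tree):
        tree, a, b = two_taxon_tree
        eff = {a: 0.05, b: 0.05}
        m = CharacterMatrix(["A", "B"], [[0], [1]], [2])
        spec = mk_spec(acrv_kind="none", n_rate_categories=1)
        ll = lk.matrix_log_likelihood(tree, eff, m, spec, ascertainment=False)
        assert math.exp(ll) == pytest.approx(0.04532, abs=1e-5)

    def test_two_taxon_corrected_symmetry(self, two_taxon_tree):
        """The two variable binary patterns are equiprobable and exhaust the
        variable-pattern space, so each corrected likelihood is 1/2."""
        tree, a, b = two_taxon_tree
        for la, lb in [(0.05, 0.05), (0.3, 0.8), (1.5, 0.01)]:
            eff = {a: la, b: lb}
            m = CharacterMatrix(["A", "B"], [[0], [1]], [2])
            ll = lk.matrix_log_likelihood(tree, eff, m, mk_spec(), ascertainment=True)
            assert math.exp(ll) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("kind,freq,k", [
        ("gamma", "symmetric", 2), ("lognormal", "symmetric", 2),
        ("gamma", "asymmetric", 2), ("none", "symmetric", 3),
        ("gamma", "symmetric", 3), ("gamma", "asymmetric", 3),
    ])
    def test_pruning_equals_enumeration(self, kind, freq, k, rng):
        """Pruning likelihood equals brute-force enumeration over interior
        states on a 5-taxon tree, for every model variant."""
        taxa = list("ABCDE")
        tree = random_calibrated_tree({t: 0.0 for t in taxa}, 10.0, rng)
        eff = {n: rng.uniform(0.02, 0.6)
               for n in tree.preorder() if n.parent is not None}
        cells = []
        for i in range(5):
            row = [int(rng.integers(k)) for _ in range(3)]
            cells.append(row)
        cells[0][0], cells[1][0] = 0, 1  # ensure variability
        cells[0][1], cells[1][1] = 0, 1
        cells[0][2], cells[1][2] = 0, 1
        cells[2][0] = None
        cells[3][1] = frozenset({0, 1})
        m = CharacterMatrix(taxa, cells, [k] * 3)
        spec = mk_spec(acrv_kind=kind, acrv_shape=0.8, n_rate_categories=3,
                       freq_model=freq, alpha_dir=1.1, n_freq_categories=3)
        got = lk.matrix_log_likelihood(tree, eff, m, spec, ascertainment=True)
        want = _brute_force_loglik(tree, eff, m, spec, ascertainment=True)
        assert got == pytest.approx(want, abs=1e-9)

    def test_constant_character_rejected(self, two_taxon_tree):
        tree, a, b = two_taxon_tree
        m = CharacterMatrix(["A", "B"], [[0], [0]], [2])
        with pytest.raises(ValueError, match="constant"):
            lk.matrix_log_likelihood(tree, {a: 0.1, b: 0.1}, m, mk_spec())

    def test_missing_taxon_rejected(self, two_taxon_tree):
        tree, a, b = two_taxon_tree
        m = CharacterMatrix(["A", "Z"], [[0], [1]], [2])
        with pytest.raises(ValueError, match="absent"):
            lk.matrix_log_likelihood(tree, {a: 0.1, b: 0.1}, m, mk_spec())

    def test_all_missing_column_is_uninformative(self, two_taxon_tree):
        """An all-missing character contributes exactly the ascertainment
        term log(1 / (1 - P_const)) of its state-count class."""
        tree, a, b = two_taxon_tree
        eff = {a: 0.1, b: 0.2}
        spec = mk_spec()
        m = CharacterMatrix(["A", "B"], [[None, 0], [None, 1]], [2, 2])
        both = lk.matrix_log_likelihood(tree, eff, m, spec, ascertainment=True)
        informative = CharacterMatrix(["A", "B"], [[0], [1]], [2])
        one = lk.matrix_log_likelihood(tree, eff, informative, spec,
                                       ascertainment=True)
        # P(variable) = P(01) + P(10) = 2 P(01) by symmetry; P_const = 1 - that
        p01 = math.exp(lk.matrix_log_likelihood(tree, eff, informative, spec,
                                                ascertainment=False))
        expected_extra = -math.log(2.0 * p01)
        assert both - one == pytest.approx(expected_extra, abs=1e-9)
        assert both > one  # the extra term is positive

    def test_uncorrected_likelihood_monotone_toward_stationarity(self, two_taxon_tree):
        """For the variable 2-taxon pattern the uncorrected likelihood is
        continuous and monotone in nu, approaching 1/4 at stationarity."""
        tree, a, b = two_taxon_tree
        m = CharacterMatrix(["A", "B"], [[0], [1]], [2])
        spec = mk_spec(acrv_kind="none", n_rate_categories=1)
        nus = np.linspace(0.01, 8.0, 60)
        lls = np.array([lk.matrix_log_likelihood(tree, {a: nu, b: nu}, m, spec,
                                                 ascertainment=False)
                        for nu in nus])
        assert np.all(np.isfinite(lls))
        assert np.all(np.diff(lls) > 0)  # rises toward the stationary value
        assert math.exp(lls[-1]) == pytest.approx(0.25, abs=1e-3)

    def test_asymmetric_high_alpha_matches_symmetric(self, rng):
        """At alpha_dir = 20 the asymmetric mixture is nearly symmetric."""
        taxa = list("ABCD")
        tree = random_calibrated_tree({t: 0.0 for t in taxa}, 5.0, rng)
        eff = {n: rng.uniform(0.05, 0.4)
               for n in tree.preorder() if n.parent is not None}
        cells = [[0, 0], [0, 1], [1, 0], [1, 1]]
        m = CharacterMatrix(taxa, cells, [2, 2])
        sym = lk.matrix_log_likelihood(
            tree, eff, m, mk_spec(freq_model="symmetric"))
        asym = lk.matrix_log_likelihood(
            tree, eff, m, mk_spec(freq_model="asymmetric", alpha_dir=20.0,
                                  n_freq_categories=4))
        assert abs(sym - asym) < 0.1


def test_pattern_probabilities_sum_to_one(four_taxon_tree, rng):
    """Corrected pattern probabilities over all variable patterns sum to 1."""
    eff = {n: rng.uniform(0.05, 0.5)
           for n in four_taxon_tree.preorder() if n.parent is not None}
    probs = lk.pattern_probabilities(four_taxon_tree, eff, 2,
                                     mk_spec(acrv_kind="none", n_rate_categories=1))
    assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
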