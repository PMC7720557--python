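"""Ascertainment-corrected Mkv likelihood for morphological matrices.

The k-state Markov (Mk) model assigns every state the same exchange rate; with
stationary frequencies ``pi`` the transition probabilities generalize to the
F81-style form

    P_ij(v) = exp(-beta v) * delta_ij + (1 - exp(-beta v)) * pi_j,

where ``beta = 1 / (1 - sum(pi^2))`` normalizes the expected number of
substitutions per unit branch length to one.  For uniform frequencies this
reduces to the familiar Mk matrix

    P_ii = 1/k + (k-1)/k * exp(-k v / (k-1)).

Because morphological matrices contain variable characters only, each
character's likelihood is conditioned on being variable (the "v" in Mkv):
``L_char / (1 - sum_s L_const(s))`` with one correction term per state-count
class, where the constant pseudo-patterns use exactly the same rate/frequency
mixture as the data.

Among-character rate variation (ACRV) uses equal-weight discrete categories
whose rates are category means of a mean-one gamma or lognormal density, and
asymmetric state frequencies use a quantile-midpoint discretization of the
symmetric Dirichlet (Beta for two states).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

from .io_formats import MISSING, CharacterMatrix
from .treedata import Node, TimeTree


@dataclass
class MkModelSpec:
    acrv_kind: str = "gamma"          # gamma | lognormal | none
    acrv_shape: float = 1.0           # gamma shape, or lognormal log-sd
    n_rate_categories: int = 4
    freq_model: str = "symmetric"     # symmetric | asymmetric
    alpha_dir: float = 1.0            # symmetric Dirichlet concentration
    n_freq_categories: int = 4

    def __post_init__(self):
        if self.acrv_kind not in ("gamma", "lognormal", "none"):
            raise ValueError(f"unknown ACRV kind {self.acrv_kind!r}")
        if self.acrv_kind != "none" and self.acrv_shape <= 0:
            raise ValueError("ACRV shape must be positive")
        if self.alpha_dir <= 0:
            raise ValueError("alpha_dir must be positive")


# --------------------------------------------------------------------------
# Transition probabilities
# --------------------------------------------------------------------------

def mk_transition_probability(k: int, nu: float,
                              freqs: Optional[np.ndarray] = None) -> np.ndarray:
    """k x k stochastic matrix of the Mk model after ``nu`` expected
    substitutions (uniform frequencies unless ``freqs`` is given)."""
    if k < 2:
        raise ValueError("state count must be >= 2")
    if nu < 0:
        raise ValueError("expected substitutions must be non-negative")
    if freqs is None:
        freqs = np.full(k, 1.0 / k)
    freqs = np.asarray(freqs, dtype=float)
    beta = 1.0 / (1.0 - np.sum(freqs ** 2))
    e = np.exp(-beta * nu)
    P = (1.0 - e) * np.tile(freqs, (k, 1))
    P[np.diag_indices(k)] += e
    return P


# --------------------------------------------------------------------------
# Mixture discretizations
# --------------------------------------------------------------------------

def discretize_acrv(spec: MkModelSpec) -> list[tuple[float, float]]:
    """Equal-weight (rate, weight) categories with weighted mean rate 1.

    Rates are category means (not medians) of the mean-1 gamma (shape alpha)
    or mean-1 lognormal (log-sd alpha) density.
    """
    n = spec.n_rate_categories
    if n < 1:
        raise ValueError("need at least one rate category")
    if n == 1 or spec.acrv_kind == "none":
        return [(1.0, 1.0)]
    if spec.acrv_shape <= 0:
        raise ValueError("ACRV shape must be positive")
    return _discretize_cached(spec.acrv_kind, float(spec.acrv_shape), n)


@lru_cache(maxsize=4096)
def _discretize_cached(kind: str, alpha: float, n: int) -> list[tuple[float, float]]:
    probs = np.arange(n + 1) / n
    if kind == "gamma":
        # mean-1 gamma: shape alpha, rate alpha; category mean via the
        # regularized incomplete gamma of shape alpha+1
        bounds = stats.gamma.ppf(probs, a=alpha, scale=1.0 / alpha)
        cdf1 = special.gammainc(alpha + 1.0, alpha * bounds[1:-1])
        cdf1 = np.concatenate([[0.0], cdf1, [1.0]])
        rates = n * np.diff(cdf1)
    else:  # lognormal, mean 1 on the linear scale
        sigma = alpha
        mu = -0.5 * sigma ** 2
        bounds = stats.lognorm.ppf(probs, s=sigma, scale=np.exp(mu))
        z = np.empty(n + 1)
        z[0], z[-1] = 0.0, 1.0
        with np.errstate(divide="ignore"):
            inner = (np.log(bounds[1:-1]) - mu) / sigma - sigma
        z[1:-1] = stats.norm.cdf(inner)
        rates = n * np.diff(z)
    rates = np.maximum(rates, 0.0)
    rates /= rates.mean()  # guard against quadrature round-off
    return [(float(r), 1.0 / n) for r in rates]


def asymmetric_frequency_mixture(k: int, alpha_dir: float,
                                 n_categories: int) -> list[tuple[np.ndarray, float]]:
    """Discrete approximation of the symmetric Dirichlet over state
    frequencies.

    For ``k == 2`` the categories are quantile midpoints of
    ``Beta(alpha, alpha)`` (symmetric about 0.5).  For ``k > 2`` each category
    places a ``Beta(alpha, (k-1) alpha)`` quantile-midpoint mass on one focal
    state and splits the remainder evenly, rotated over all focal states so
    the category-weighted mean is exactly uniform.
    """
    if k < 2:
        raise ValueError("state count must be >= 2")
    if alpha_dir <= 0:
        raise ValueError("alpha_dir must be positive")
    mids = (np.arange(n_categories) + 0.5) / n_categories
    if k == 2:
        p = stats.beta.ppf(mids, alpha_dir, alpha_dir)
        return [(np.array([pi, 1.0 - pi]), 1.0 / n_categories) for pi in p]
    p = stats.beta.ppf(mids, alpha_dir, (k - 1) * alpha_dir)
    cats = []
    w = 1.0 / (n_categories * k)
    for pi in p:
        for focal in range(k):
            vec = np.full(k, (1.0 - pi) / (k - 1))
            vec[focal] = pi
            cats.append((vec, w))
    return cats


# --------------------------------------------------------------------------
# Pruning likelihood
# --------------------------------------------------------------------------

def _tip_partials(matrix: CharacterMatrix, char_idx: Sequence[int], k: int) -> dict[str, np.ndarray]:
    """Per-taxon (k, n_chars) indicator partials for a state-count class."""
    out = {}
    for i, taxon in enumerate(matrix.taxon_names):
        arr = np.zeros((k, len(char_idx)))
        for col, j in enumerate(char_idx):
            c = matrix.cells[i][j]
            if c is MISSING:
                arr[:, col] = 1.0
            elif isinstance(c, frozenset):
                for s in c:
                    arr[s, col] = 1.0
            else:
                arr[c, col] = 1.0
        out[taxon] = arr
    return out


class LikelihoodEngine:
    """Precompiled Mkv pruning for one matrix.

    Tip partials and state-count classes are built once; each evaluation
    propagates all rate (and frequency) categories in a single broadcast
    pass, with the k constant pseudo-patterns of the ascertainment
    correction riding along as extra columns.  The Mk/F81 action
    ``P v = e^{-beta r nu} v + (1 - e^{-beta r nu}) (pi . v)`` is applied in
    closed form without building transition matrices.
    """

    def __init__(self, matrix: CharacterMatrix, ascertainment: bool = True):
        self.matrix = matrix
        self.ascertainment = ascertainment
        self.taxa = set(matrix.taxon_names)
        if ascertainment:
            for j in range(matrix.n_characters):
                if not matrix.is_variable(j):
                    if all(matrix.cells[i][j] is None
                           for i in range(matrix.n_taxa)):
                        import warnings
                        warnings.warn(f"character {j} is entirely missing; "
                                      "it contributes only the ascertainment term")
                        continue
                    raise ValueError(
                        f"character {j} is constant; Mkv requires variable characters")
        self.classes: dict[int, list[int]] = {}
        for j, k in enumerate(matrix.char_state_counts):
            self.classes.setdefault(k, []).append(j)
        # augmented partials: (k, n_chars + k), identity columns = constant
        # pseudo-patterns for the ascertainment denominator
        self.aug: dict[int, dict[str, np.ndarray]] = {}
        for k, idx in self.classes.items():
            partials = _tip_partials(matrix, idx, k)
            self.aug[k] = {t: np.concatenate([p, np.eye(k)], axis=1)
                           for t, p in partials.items()}

    def log_likelihood(self, tree: TimeTree, eff_len: dict[Node, float],
                       spec: MkModelSpec) -> float:
        missing = self.taxa - set(n.taxon for n in tree.leaves())
        if missing:
            raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")
        nodes = list(tree.postorder())
        total = 0.0
        rate_cats = discretize_acrv(spec)
        rates = np.array([r for r, _ in rate_cats])[:, None, None]
        rw = np.array([w for _, w in rate_cats])
        for k, idx in sorted(self.classes.items()):
            n_chars = len(idx)
            if spec.freq_model == "asymmetric":
                freq_cats = asymmetric_frequency_mixture(
                    k, spec.alpha_dir, spec.n_freq_categories)
            else:
                freq_cats = [(np.full(k, 1.0 / k), 1.0)]
            aug = self.aug[k]
            n_cols = n_chars + k
            like = np.zeros(n_chars)
            const = 0.0
            for freqs, fw in freq_cats:
                beta = 1.0 / (1.0 - float(freqs @ freqs))
                down: dict[Node, np.ndarray] = {}
                log_scale = np.zeros(n_cols)
                for node in nodes:
                    if node.is_leaf:
                        part = aug[node.taxon]  # (k, n_cols), broadcast over rates
                    else:
                        part = None
                        for child in node.children:
                            v = down[child]
                            e = np.exp(-beta * eff_len[child] * rates)  # (R,1,1)
                            if v.ndim == 2:       # leaf partial (k, n_cols)
                                fv = freqs @ v    # (n_cols,)
                                pv = e * v + (1.0 - e) * fv
                            else:                 # (R, k, n_cols)
                                fv = np.einsum("j,rjc->rc", freqs, v)
                                pv = e * v + (1.0 - e) * fv[:, None, :]
                            part = pv if part is None else part * pv
                        mx = part.max(axis=(0, 1))
                        mx[mx <= 0] = 1.0
                        part = part / mx
                        log_scale += np.log(mx)
                    down[node] = part
                root = down[tree.root]
                cat_like = np.einsum("j,rjc->rc", freqs, root)  # (R, n_cols)
                mixed = (rw @ cat_like) * np.exp(log_scale)
                like += fw * mixed[:n_chars]
                const += fw * float(mixed[n_chars:].sum())
            if np.any(like <= 0):
                return -np.inf
            logl = np.log(like)
            if self.ascertainment:
                if const >= 1.0:
                    return -np.inf
                logl = logl - np.log1p(-const)
            total += float(np.sum(logl))
        return total


def matrix_log_likelihood(tree: TimeTree, eff_len: dict[Node, float],
                          matrix: CharacterMatrix, spec: MkModelSpec,
                          ascertainment: bool = True) -> float:
    """Mkv log-likelihood of ``matrix`` on ``tree`` with per-node expected
    substitution branch lengths ``eff_len``.

    Characters are grouped by their state-count class; the variable-only
    ascertainment denominator ``1 - sum_s P(constant s)`` is shared within a
    class because characters are exchangeable under Mk.
    """
    return LikelihoodEngine(matrix, ascertainment).log_likelihood(tree, eff_len, spec)


def pattern_probabilities(tree: TimeTree, eff_len: dict[Node, float], k: int,
                          spec: MkModelSpec, ascertainment: bool = True) -> dict[tuple, float]:
    """Probability of every complete tip pattern (small trees only).

    Used to cross-check simulators and the pruning implementation; patterns
    are keyed by tip states in ``sorted(taxa)`` order.
    """
    import itertools

    taxa = sorted(n.taxon for n in tree.leaves())
    out = {}
    for pattern in itertools.product(range(k), repeat=len(taxa)):
        cm = CharacterMatrix(
            taxon_names=list(taxa),
            cells=[[s] for s in pattern],
            char_state_counts=[k],
        )
        if ascertainment and not cm.is_variable(0):
            continue
        out[pattern] = float(np.exp(matrix_log_likelihood(
            tree, eff_len, cm, spec, ascertainment=ascertainment)))
    return out
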