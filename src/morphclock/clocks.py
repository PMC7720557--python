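"""Relaxed and strict morphological clocks.

All clocks convert branch *durations* (Myr) into *effective branch lengths*
(expected substitutions per character) around a base rate ``c``
(substitutions/character/Myr):

strict
    ``v_b = c * t_b`` exactly.
igr (uncorrelated, independent gamma rates)
    Each ``v_b`` is a free parameter with prior
    ``Gamma(mean = c t_b, variance = c t_b * nu)``; as ``nu -> 0`` the prior
    collapses onto the strict-clock expectation.
tk02 (autocorrelated, geometric Brownian rates)
    Node rates evolve along the tree: the child rate is lognormal with
    linear-scale expectation equal to the parent rate and log-variance
    ``nu * t_b``; the branch rate is the arithmetic mean of its endpoint
    rates, so ``v_b = t_b (r_parent + r_child) / 2``.  The root rate equals
    the base rate.

The base-rate prior follows the tree-height construction: the median tree
height in substitutions from a non-clock analysis divided by the median root
age gives the prior mean; the lognormal variant takes its log-sd as
``exp(mean)`` and the gamma variant a fixed sd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

_SQRT2PI = math.sqrt(2.0 * math.pi)

from .treedata import Node, TimeTree


@dataclass
class BaseRatePrior:
    kind: str  # lognormal | gamma
    mean: float
    sd: float  # log-sd for lognormal, linear sd for gamma

    def log_density(self, c: float) -> float:
        if c <= 0:
            return -np.inf
        if self.kind == "lognormal":
            z = (math.log(c) - math.log(self.mean)) / self.sd
            return -math.log(c * self.sd * _SQRT2PI) - 0.5 * z * z
        shape = (self.mean / self.sd) ** 2
        rate = self.mean / self.sd ** 2
        return (shape * math.log(rate) - math.lgamma(shape)
                + (shape - 1.0) * math.log(c) - rate * c)

    def sample(self, rng) -> float:
        if self.kind == "lognormal":
            return float(self.mean * np.exp(self.sd * rng.standard_normal()))
        shape = (self.mean / self.sd) ** 2
        return float(rng.gamma(shape, self.sd ** 2 / self.mean))


def derive_clock_prior(tree_height_substitutions: float,
                       root_age_prior_median: float,
                       gamma_sd: float = 0.5) -> dict:
    """Informative base-rate prior from a non-clock tree height.

    Returns the prior mean (height / root age) together with the implied
    lognormal parameters (log-mean = ln(ratio); log-sd = exp(ratio)) and the
    (mean, sd) gamma parameterization.
    """
    if tree_height_substitutions <= 0 or root_age_prior_median <= 0:
        raise ValueError("tree height and root age must be positive")
    ratio = tree_height_substitutions / root_age_prior_median
    return {
        "mean": ratio,
        "lognormal": BaseRatePrior("lognormal", mean=ratio, sd=math.exp(ratio)),
        "lognormal_logmean": math.log(ratio),
        "lognormal_logsd": math.exp(ratio),
        "gamma": BaseRatePrior("gamma", mean=ratio, sd=gamma_sd),
    }


@dataclass
class ClockState:
    """All continuous state of one morphological clock."""

    model: str  # strict | igr | tk02 | none
    base_rate: float
    variance: float = 0.0
    branch_values: dict[Node, float] = field(default_factory=dict)
    # igr/none: branch_values are effective lengths; tk02: per-node rates

    def copy_for(self, node_map: dict[Node, Node]) -> "ClockState":
        return ClockState(
            self.model, self.base_rate, self.variance,
            {node_map[n]: v for n, v in self.branch_values.items() if n in node_map},
        )


# --------------------------------------------------------------------------
# Effective lengths + prior densities
# --------------------------------------------------------------------------

def strict_effective_lengths(tree: TimeTree, c: float) -> dict[Node, float]:
    return {n: c * tree.duration(n) for n in tree.preorder() if n.parent is not None}


def igr_branch_log_prior(t: float, c: float, nu: float, v: float) -> float:
    """Log-density of one IGR effective length."""
    mean = c * t
    if nu <= 0 or t <= 0:
        # degenerate: point mass at the strict-clock value
        return 0.0 if abs(v - mean) <= 1e-9 * max(mean, 1.0) else -np.inf
    if v < 0:
        return -np.inf
    shape = mean / nu          # Gamma(mean = c t, variance = c t nu)
    rate = 1.0 / nu
    if v == 0:
        return -np.inf if shape > 0 else 0.0
    return (shape * math.log(rate) - math.lgamma(shape)
            + (shape - 1.0) * math.log(v) - rate * v)


def igr_effective_lengths(tree: TimeTree, state: ClockState,
                          rng=None) -> tuple[dict[Node, float], float]:
    """(effective lengths, log-prior) under the uncorrelated gamma clock.

    If ``rng`` is given, missing branch values are drawn from their prior
    (used for initialization and reversible-jump auxiliary draws).
    """
    c, nu = state.base_rate, state.variance
    eff: dict[Node, float] = {}
    log_prior = 0.0
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = tree.duration(node)
        if node not in state.branch_values:
            if rng is None:
                raise ValueError("missing IGR branch value and no rng to draw one")
            state.branch_values[node] = sample_igr_branch(t, c, nu, rng)
        v = state.branch_values[node]
        if t <= 1e-12:
            # sampled-ancestor attachment: zero duration forces zero length
            eff[node] = 0.0
            if v > 1e-12:
                log_prior = -np.inf
            continue
        eff[node] = v
        log_prior += igr_branch_log_prior(t, c, nu, v)
    return eff, log_prior


def sample_igr_branch(t: float, c: float, nu: float, rng) -> float:
    mean = c * t
    if t <= 1e-12:
        return 0.0
    if nu <= 1e-12:
        return mean
    shape = mean / nu
    # guard against underflow to exactly zero at very small shapes
    return float(max(rng.gamma(shape, nu), 1e-12))


def tk02_node_log_prior(r_child: float, r_parent: float, nu: float, t: float) -> float:
    """Lognormal increment density: E[r_child | r_parent] = r_parent,
    log-variance nu * t."""
    if r_child <= 0 or r_parent <= 0:
        return -np.inf
    var = nu * t
    if var <= 0:
        return 0.0 if abs(r_child - r_parent) <= 1e-9 * r_parent else -np.inf
    sd = math.sqrt(var)
    mu = math.log(r_parent) - 0.5 * var
    z = (math.log(r_child) - mu) / sd
    return -math.log(r_child * sd * _SQRT2PI) - 0.5 * z * z


def tk02_effective_lengths(tree: TimeTree, state: ClockState,
                           rng=None) -> tuple[dict[Node, float], float]:
    """(effective lengths, log-prior) under the autocorrelated lognormal clock.

    ``state.branch_values`` holds per-node rates; the root rate is pinned to
    the base rate.  Zero-duration branches (sampled-ancestor attachments)
    force the child rate onto the parent rate and contribute no density.
    """
    c, nu = state.base_rate, state.variance
    rates: dict[Node, float] = {tree.root: c}
    eff: dict[Node, float] = {}
    log_prior = 0.0
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = tree.duration(node)
        r_parent = rates[node.parent]
        if t <= 1e-12:
            rates[node] = r_parent
            state.branch_values[node] = r_parent
            eff[node] = 0.0
            continue
        if node not in state.branch_values:
            if rng is None:
                raise ValueError("missing TK02 node rate and no rng to draw one")
            state.branch_values[node] = sample_tk02_rate(r_parent, nu, t, rng)
        r = state.branch_values[node]
        rates[node] = r
        eff[node] = t * 0.5 * (r_parent + r)
        log_prior += tk02_node_log_prior(r, r_parent, nu, t)
    return eff, log_prior


def sample_tk02_rate(r_parent: float, nu: float, t: float, rng) -> float:
    var = nu * t
    if var <= 0:
        return r_parent
    mu = math.log(r_parent) - 0.5 * var
    return float(math.exp(mu + math.sqrt(var) * rng.standard_normal()))


def effective_lengths(tree: TimeTree, state: ClockState,
                      rng=None) -> tuple[dict[Node, float], float]:
    """Dispatch on the clock model; returns (lengths, clock log-prior)."""
    if state.model == "strict":
        return strict_effective_lengths(tree, state.base_rate), 0.0
    if state.model == "igr":
        return igr_effective_lengths(tree, state, rng)
    if state.model == "tk02":
        return tk02_effective_lengths(tree, state, rng)
    if state.model == "none":
        # non-clock mode: free branch lengths with Exponential priors
        eff = {}
        log_prior = 0.0
        for node in tree.preorder():
            if node.parent is None:
                continue
            if node not in state.branch_values:
                if rng is None:
                    raise ValueError("missing branch length")
                state.branch_values[node] = float(rng.exponential(1.0 / state.variance))
            v = state.branch_values[node]
            if v < 0:
                return eff, -np.inf
            eff[node] = v
            log_prior += math.log(state.variance) - state.variance * v
        return eff, log_prior
    raise ValueError(f"unknown clock model {state.model!r}")


# --------------------------------------------------------------------------
# Partitioned clocks
# --------------------------------------------------------------------------

@dataclass
class PartitionClockScheme:
    """One clock per anatomical partition on a shared time tree."""

    states: dict[str, ClockState]

    def __post_init__(self):
        if not self.states:
            raise ValueError("need at least one partition clock")


def check_partition_sizes(n_taxa: int, sizes: dict[str, int]) -> list[str]:
    """Partitions smaller than the 2n-1 change-budget bound (one expected
    change per tree branch) are flagged; returns the list of warnings."""
    bound = 2 * n_taxa - 1
    warnings = []
    for label, size in sizes.items():
        if size < 1:
            raise ValueError(f"partition {label!r} is empty")
        if size < bound:
            warnings.append(
                f"partition {label!r} has {size} characters < 2n-1 = {bound}"
            )
    return warnings


def apply_partition_clocks(tree: TimeTree, scheme: PartitionClockScheme,
                           rng=None) -> tuple[dict[str, dict[Node, float]], float]:
    """Per-partition effective lengths plus the summed clock log-prior."""
    out = {}
    log_prior = 0.0
    for label, state in scheme.states.items():
        eff, lp = effective_lengths(tree, state, rng)
        out[label] = eff
        log_prior += lp
    return out, log_prior
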