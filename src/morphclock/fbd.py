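"""Fossilized birth-death (FBD) tree priors, constant-rate and skyline.

Parameterization follows the (d, r, s) convention: net diversification
``d = lambda - mu`` (events/Myr), turnover ``r = mu / lambda`` and fossil
sampling proportion ``s = psi / (mu + psi)``, with extant sampling
probability ``rho``.  The canonical rates are recovered as
``lambda = d/(1-r)``, ``mu = lambda r``, ``psi = mu s/(1-s)``.

The density uses the standard auxiliary functions

    c1 = |sqrt((lambda - mu - psi)^2 + 4 lambda psi)|
    c2 = -(lambda - mu - 2 lambda rho - psi) / c1
    q(t) = 4 e^{-c1 t} / (e^{-c1 t}(1 - c2) + (1 + c2))^2
    p0(t) = [lambda + mu + psi
             + c1 (e^{-c1 t}(1-c2) - (1+c2)) / (e^{-c1 t}(1-c2) + (1+c2))]
            / (2 lambda)

where ``p0(t)`` is the probability that a lineage alive at time ``t`` leaves
no sampled descendants and ``q(s)/q(e)`` is the density contribution of an
observed lineage spanning ``(s, e)``.  In the skyline generalization the
parameters are piecewise constant between shift times and ``p0``/``q`` are
chained continuously across slice boundaries.

The density is assembled per event: ``lambda`` for every birth node (the
root's split is conditioned on, not scored), ``psi`` for every fossil
sampling event, ``psi p0(y)`` for fossil tips, ``rho`` per extant tip, and
``q``-ratios along every observed edge; it is conditioned on the root age
and on both root lineages leaving at least one sampled descendant.

Under diversified extant sampling all speciation events and fossils in the
sampled tree predate the cutoff ``x_cut``; the extant-sampling binomial term
is replaced by the probability that each lineage crossing ``x_cut`` survives
to the present, with ``q`` integrated only down to ``x_cut``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .io_formats import CalibrationTable
from .treedata import Node, TimeTree

_EPS = 1e-12


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

@dataclass
class FBDParams:
    d: float           # net diversification, events/Myr
    r: float           # turnover mu/lambda in [0, 1)
    s: float           # fossil-sampling proportion psi/(mu+psi) in [0, 1)
    rho: float = 1.0   # extant-sampling probability in (0, 1]

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("net diversification must be positive")
        if not (0 <= self.r < 1):
            raise ValueError("turnover must be in [0, 1)")
        if not (0 <= self.s < 1):
            raise ValueError("fossil-sampling proportion must be in [0, 1)")
        if not (0 < self.rho <= 1):
            raise ValueError("extant-sampling probability must be in (0, 1]")

    def canonical(self) -> tuple[float, float, float]:
        return to_canonical(self.d, self.r, self.s)


def to_canonical(d: float, r: float, s: float) -> tuple[float, float, float]:
    """(d, r, s) -> (lambda, mu, psi)."""
    if r >= 1 or s >= 1:
        raise ValueError("turnover and fossil proportion must be < 1")
    if d <= 0:
        raise ValueError("net diversification must be positive")
    lam = d / (1.0 - r)
    mu = lam * r
    psi = mu * s / (1.0 - s) if s > 0 else 0.0
    return lam, mu, psi


def from_canonical(lam: float, mu: float, psi: float) -> tuple[float, float, float]:
    """(lambda, mu, psi) -> (d, r, s); inverse of :func:`to_canonical`."""
    d = lam - mu
    r = mu / lam
    s = psi / (mu + psi) if (mu + psi) > 0 else 0.0
    return d, r, s


@dataclass
class SamplingStrategy:
    kind: str  # fossiltip | random | diversity | nosa_diversity
    x_cut: float = 0.0

    def __post_init__(self):
        if self.kind not in ("fossiltip", "random", "diversity", "nosa_diversity"):
            raise ValueError(f"unknown sampling strategy {self.kind!r}")
        if self.diversified and self.x_cut <= 0:
            raise ValueError("diversity strategies need x_cut > 0")

    @property
    def sampled_ancestors_allowed(self) -> bool:
        return self.kind in ("random", "diversity")

    @property
    def diversified(self) -> bool:
        return self.kind in ("diversity", "nosa_diversity")


@dataclass
class SkylineGrid:
    """Piecewise-constant FBD parameters.

    ``shift_times`` are strictly decreasing ages (Ma); ``slices`` holds one
    :class:`FBDParams` per time slice ordered oldest first, so slice 0 spans
    (root age, t_1], slice i spans (t_i, t_{i+1}] and the last slice reaches
    the present.  A fossil exactly at a boundary belongs to the older slice.
    ``free_mask`` is ``"s"`` (only fossil sampling shifts) or ``"sdr"``.
    """

    shift_times: tuple[float, ...]
    slices: list[FBDParams]
    free_mask: str = "sdr"
    x_cut: float = 0.0

    def __post_init__(self):
        if len(self.slices) != len(self.shift_times) + 1:
            raise ValueError("need exactly one slice more than shift times")
        if any(t2 >= t1 for t1, t2 in zip(self.shift_times, self.shift_times[1:])):
            raise ValueError("shift times must be strictly decreasing")
        if any(t <= 0 for t in self.shift_times):
            raise ValueError("shift times must be positive ages")
        if self.free_mask not in ("s", "sdr"):
            raise ValueError("free_mask must be 's' or 'sdr'")
        if self.free_mask == "s":
            d0, r0 = self.slices[0].d, self.slices[0].r
            for p in self.slices[1:]:
                if abs(p.d - d0) > 1e-12 or abs(p.r - r0) > 1e-12:
                    raise ValueError("with mask 's', d and r must be shared across slices")

    @classmethod
    def constant(cls, params: FBDParams) -> "SkylineGrid":
        return cls(shift_times=(), slices=[params], free_mask="sdr")

    def n_free_parameters(self) -> int:
        l = len(self.slices)
        return 3 * l if self.free_mask == "sdr" else l + 2

    def slice_index(self, age: float) -> int:
        """Oldest-first slice index of an event at ``age``; boundaries are
        closed on the old side."""
        for i, t in enumerate(self.shift_times):
            if age >= t:
                return i
        return len(self.slices) - 1


# --------------------------------------------------------------------------
# Piecewise p0 / q machinery
# --------------------------------------------------------------------------

class _SlicedFunctions:
    """p0(t) and log q(t) for piecewise-constant (lambda, mu, psi) with
    extant sampling ``rho`` at the present."""

    def __init__(self, boundaries_asc: list[float], params_young_first: list[tuple],
                 rho: float):
        # boundaries_asc[i] is the lower (younger) edge of slice i
        self.bnd = boundaries_asc
        self.par = params_young_first
        self.A: list[float] = []
        self.B: list[float] = []
        self.logC: list[float] = [0.0]
        p_lower = 1.0 - rho
        for i, (lam, mu, psi) in enumerate(self.par):
            A = math.sqrt(max((lam - mu - psi) ** 2 + 4.0 * lam * psi, _EPS))
            B = ((1.0 - 2.0 * p_lower) * lam + mu + psi) / A
            self.A.append(A)
            self.B.append(B)
            if i + 1 < len(self.par):
                width = self.bnd[i + 1] - self.bnd[i]
                p_lower = self._p0_in_slice(i, width)
                self.logC.append(self.logC[-1] + self._logq_in_slice(i, width))

    def _slice_of(self, t: float) -> int:
        for i in range(len(self.par) - 1, 0, -1):
            if t >= self.bnd[i] - _EPS:
                return i
        return 0

    def _p0_in_slice(self, i: int, dt: float) -> float:
        lam, mu, psi = self.par[i]
        A, B = self.A[i], self.B[i]
        e = math.exp(-A * dt)
        h = ((1.0 + B) - e * (1.0 - B)) / ((1.0 + B) + e * (1.0 - B))
        return (lam + mu + psi - A * h) / (2.0 * lam)

    def _logq_in_slice(self, i: int, dt: float) -> float:
        A, B = self.A[i], self.B[i]
        e = math.exp(-A * dt)
        return math.log(4.0) - A * dt - 2.0 * math.log((1.0 + B) + e * (1.0 - B))

    def p0(self, t: float) -> float:
        i = self._slice_of(t)
        return self._p0_in_slice(i, t - self.bnd[i])

    def logq(self, t: float) -> float:
        i = self._slice_of(t)
        return self.logC[i] + self._logq_in_slice(i, t - self.bnd[i])


def _build_functions(grid: SkylineGrid, rho: float,
                     extinction_only: bool = False) -> _SlicedFunctions:
    boundaries = [0.0] + sorted(grid.shift_times)
    young_first = list(reversed(grid.slices))
    params = []
    for p in young_first:
        lam, mu, psi = p.canonical()
        if extinction_only:
            params.append((lam, mu, 0.0))
        else:
            params.append((lam, mu, psi))
    return _SlicedFunctions(boundaries, params, 1.0 if extinction_only else rho)


# --------------------------------------------------------------------------
# Node classification and the density
# --------------------------------------------------------------------------

def _classify(tree: TimeTree):
    birth_nodes, sa_tips, fossil_tips, extant_tips = [], [], [], []
    for node in tree.preorder():
        if node.is_leaf:
            if node.age <= 1e-9:
                extant_tips.append(node)
            elif tree.is_sampled_ancestor(node):
                sa_tips.append(node)
            else:
                fossil_tips.append(node)
        else:
            if not tree.sa_attachment(node):
                birth_nodes.append(node)
    return birth_nodes, sa_tips, fossil_tips, extant_tips


def skyline_fbd_log_density(tree: TimeTree, grid: SkylineGrid,
                            strategy: SamplingStrategy,
                            condition_on_survival: bool = True) -> float:
    """Log-density of a calibrated tree under the (skyline) FBD prior,
    conditioned on the root age."""
    root_age = tree.root.age
    if grid.shift_times and grid.shift_times[0] >= root_age:
        raise ValueError("shift time older than the root age")
    rho = grid.slices[0].rho
    birth_nodes, sa_tips, fossil_tips, extant_tips = _classify(tree)

    if sa_tips and not strategy.sampled_ancestors_allowed:
        return -np.inf
    if strategy.diversified:
        xc = strategy.x_cut
        if any(t.age < xc - _EPS for t in sa_tips + fossil_tips):
            return -np.inf
        if any(n.age < xc - _EPS for n in birth_nodes if n is not tree.root):
            return -np.inf
        if tree.root.age < xc:
            return -np.inf

    fn = _build_functions(grid, rho)
    lam_of = lambda age: grid.slices[grid.slice_index(age)].canonical()[0]
    psi_of = lambda age: grid.slices[grid.slice_index(age)].canonical()[2]

    logp = 0.0
    # q-ratio along every observed edge
    for node in tree.preorder():
        if node.parent is None:
            continue
        lower = node.age
        if strategy.diversified and node.is_leaf and node.age <= 1e-9:
            lower = strategy.x_cut
        logp += fn.logq(node.parent.age) - fn.logq(lower)
    # birth events (the root split is conditioned on)
    for node in birth_nodes:
        if node is tree.root:
            continue
        lam = lam_of(node.age)
        if lam <= 0:
            return -np.inf
        logp += math.log(lam)
    # fossil sampling events
    for tip in sa_tips + fossil_tips:
        psi = psi_of(tip.age)
        if psi <= 0:
            return -np.inf
        logp += math.log(psi)
    for tip in fossil_tips:
        p0 = fn.p0(tip.age)
        if p0 <= 0:
            return -np.inf
        logp += math.log(p0)
    # extant sampling
    if strategy.diversified:
        ext = _build_functions(grid, rho, extinction_only=True)
        surv = 1.0 - ext.p0(strategy.x_cut)
        if surv <= 0:
            return -np.inf
        logp += len(extant_tips) * math.log(surv)
        if condition_on_survival:
            root_surv = 1.0 - ext.p0(root_age)
            if root_surv <= 0:
                return -np.inf
            logp -= 2.0 * math.log(root_surv)
    else:
        logp += len(extant_tips) * math.log(rho)
        if condition_on_survival:
            surv = 1.0 - fn.p0(root_age)
            if surv <= 0:
                return -np.inf
            logp -= 2.0 * math.log(surv)
    if not np.isfinite(logp):
        return -np.inf
    return float(logp)


def fbd_log_density(tree: TimeTree, params: FBDParams, strategy: SamplingStrategy,
                    condition_on_survival: bool = True) -> float:
    """Constant-rate FBD log-density (single-slice skyline)."""
    return skyline_fbd_log_density(
        tree, SkylineGrid.constant(params), strategy, condition_on_survival
    )


# --------------------------------------------------------------------------
# Root and tip calibration priors
# --------------------------------------------------------------------------

@dataclass
class RootCalibration:
    kind: str                      # offset_exponential | truncated_normal
    params: tuple[float, ...]      # (offset, mean) or (mean, sd, min, max)

    def __post_init__(self):
        if self.kind == "offset_exponential":
            offset, mean = self.params
            if offset >= mean:
                raise ValueError("offset must lie below the mean")
        elif self.kind == "truncated_normal":
            _, sd, lo, hi = self.params
            if sd <= 0 or lo >= hi:
                raise ValueError("need sd > 0 and min < max")
        else:
            raise ValueError(f"unknown root calibration {self.kind!r}")

    def log_density(self, age: float) -> float:
        if self.kind == "offset_exponential":
            offset, mean = self.params
            if age < offset:
                return -np.inf
            rate = 1.0 / (mean - offset)
            return math.log(rate) - rate * (age - offset)
        mean, sd, lo, hi = self.params
        if not (lo <= age <= hi):
            return -np.inf
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return float(stats.truncnorm.logpdf(age, a, b, loc=mean, scale=sd))

    def sample(self, rng) -> float:
        if self.kind == "offset_exponential":
            offset, mean = self.params
            return float(offset + rng.exponential(mean - offset))
        mean, sd, lo, hi = self.params
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                         random_state=np.random.RandomState(rng.integers(2**31))))


def root_and_tip_log_priors(tree: TimeTree, root_cal: RootCalibration,
                            calibrations: CalibrationTable) -> float:
    """Root calibration density plus uniform tip-age densities."""
    logp = root_cal.log_density(tree.root.age)
    for leaf in tree.leaves():
        cal = calibrations[leaf.taxon]
        if cal.is_extant:
            if leaf.age > 1e-9:
                raise ValueError(f"extant tip {leaf.taxon} has nonzero age {leaf.age}")
            continue
        width = cal.age_max - cal.age_min
        if not (cal.age_min - _EPS <= leaf.age <= cal.age_max + _EPS):
            return -np.inf
        logp += -math.log(width) if width > 0 else 0.0
    return float(logp)


# --------------------------------------------------------------------------
# Parameter priors for inference
# --------------------------------------------------------------------------

@dataclass
class FBDParamPriors:
    """Default priors: Exponential(rate 10) on d; Uniform(0,1) on r and s,
    or Beta(1, 9) on r in the low-extinction variant."""

    d_rate: float = 10.0
    low_extinction: bool = False

    def log_density(self, grid: SkylineGrid) -> float:
        logp = 0.0
        seen_dr = False
        for p in grid.slices:
            if not (0 <= p.r < 1) or not (0 <= p.s < 1) or p.d <= 0:
                return -np.inf
            count_dr = grid.free_mask == "sdr" or not seen_dr
            if count_dr:
                logp += math.log(self.d_rate) - self.d_rate * p.d
                if self.low_extinction:
                    logp += float(stats.beta.logpdf(min(p.r, 1 - _EPS), 1.0, 9.0))
                seen_dr = True
        return logp
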