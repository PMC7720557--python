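"""Metropolis-Hastings-within-Gibbs sampler over (tree, ages, clock,
substitution, FBD) space, with reversible-jump sampled-ancestor moves.

The state is a calibrated :class:`~morphclock.treedata.TimeTree` plus all
continuous parameters.  Every proposal acts on a copy of the state; the full
posterior (or the prior alone, or a power posterior ``prior x likelihood^b``)
is re-evaluated and the move accepted with the usual ratio including the
Hastings term.  Sampled-ancestor add/delete moves form a reversible-jump
pair: converting a fossil tip to an ancestor pins its attachment age to the
fossil age and drops the branch-specific clock variables, whose prior
densities enter the acceptance ratio; zeroing the pair's proposal weights is
exactly the "no sampled ancestors" device.

Convergence diagnostics: average standard deviation of split frequencies
(ASDSF) across runs, potential scale reduction factors (PSRF) and
autocorrelation-based effective sample sizes (ESS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import clocks, fbd, likelihood
from .io_formats import CalibrationTable, CharacterMatrix, RunConfig
from .treedata import Node, TimeTree, random_calibrated_tree


class _Reject(Exception):
    """Raised by a proposal that cannot produce a valid candidate."""


# --------------------------------------------------------------------------
# Model setup and chain state
# --------------------------------------------------------------------------

@dataclass
class ModelSetup:
    config: RunConfig
    matrix: CharacterMatrix
    calibrations: CalibrationTable
    partitions: dict[str, CharacterMatrix]
    strategy: fbd.SamplingStrategy
    root_cal: fbd.RootCalibration
    base_rate_prior: clocks.BaseRatePrior
    fbd_param_priors: fbd.FBDParamPriors
    acrv_shape_prior_rate: float = 1.0
    engines: dict[str, likelihood.LikelihoodEngine] = field(default_factory=dict)

    @classmethod
    def build(cls, config: RunConfig, matrix: CharacterMatrix,
              calibrations: CalibrationTable) -> "ModelSetup":
        calibrations.validate(matrix)
        if config.partitions:
            partitions = {}
            for label, idx in config.partitions.items():
                partitions[label] = matrix.subset(idx)
        elif matrix.partition_map:
            partitions = matrix.partition_subsets()
        else:
            partitions = {"all": matrix}
        strategy = fbd.SamplingStrategy(config.sampling_strategy, x_cut=config.x_cut)
        root_cal = fbd.RootCalibration(config.root_prior_kind, config.root_prior_params)
        mean, sd = config.base_rate_prior_params
        base_prior = clocks.BaseRatePrior(config.base_rate_prior_kind, mean, sd)
        priors = fbd.FBDParamPriors(config.diversification_prior_rate,
                                    config.low_extinction_prior)
        engines = {lab: likelihood.LikelihoodEngine(part)
                   for lab, part in partitions.items()}
        return cls(config, matrix, calibrations, partitions, strategy,
                   root_cal, base_prior, priors, engines=engines)


class ChainState:
    def __init__(self, tree: TimeTree, clock_states: dict[str, clocks.ClockState],
                 acrv_shape: dict[str, float], alpha_dir: Optional[float],
                 grid: fbd.SkylineGrid):
        self.tree = tree
        self.clocks = clock_states
        self.acrv_shape = acrv_shape
        self.alpha_dir = alpha_dir
        self.grid = grid
        self.log_likelihood = np.nan
        self.log_prior = np.nan
        self._eff: dict[str, dict[Node, float]] = {}
        self._lnl_parts: dict[str, float] = {}
        self._touched: Optional[str] = None

    def copy(self) -> "ChainState":
        node_map: dict[Node, Node] = {}

        def _clone(node: Node) -> Node:
            new = Node(node.age, node.taxon)
            new.meta = dict(node.meta)
            node_map[node] = new
            for c in node.children:
                new.add_child(_clone(c))
            return new

        tree = TimeTree(_clone(self.tree.root))
        clock_states = {lab: cs.copy_for(node_map) for lab, cs in self.clocks.items()}
        new = ChainState(tree, clock_states, dict(self.acrv_shape), self.alpha_dir,
                         fbd.SkylineGrid(self.grid.shift_times,
                                         [fbd.FBDParams(p.d, p.r, p.s, p.rho)
                                          for p in self.grid.slices],
                                         self.grid.free_mask, self.grid.x_cut))
        new.log_likelihood = self.log_likelihood
        new.log_prior = self.log_prior
        new._lnl_parts = dict(self._lnl_parts)
        return new


def mk_spec_for(setup: ModelSetup, state: ChainState, label: str) -> likelihood.MkModelSpec:
    cfg = setup.config
    return likelihood.MkModelSpec(
        acrv_kind=cfg.acrv_kind,
        acrv_shape=state.acrv_shape[label],
        n_rate_categories=cfg.n_rate_categories,
        freq_model=cfg.freq_model,
        alpha_dir=state.alpha_dir if state.alpha_dir is not None else 1.0,
        n_freq_categories=cfg.n_freq_categories,
    )


def evaluate(state: ChainState, setup: ModelSetup,
             likelihood_power: float = 1.0,
             update_labels: Optional[set] = None) -> float:
    """Recompute and cache log prior and (powered) log likelihood; returns
    the log target density.

    ``update_labels`` limits the per-partition likelihood recomputation to
    the partitions a proposal actually touched (None means all); the prior
    is always recomputed in full.
    """
    cfg = setup.config
    tree = state.tree
    try:
        log_prior = fbd.root_and_tip_log_priors(tree, setup.root_cal, setup.calibrations)
    except ValueError:
        state.log_prior = -np.inf
        return -np.inf
    if np.isfinite(log_prior) and cfg.clock_model != "none":
        log_prior += fbd.skyline_fbd_log_density(tree, state.grid, setup.strategy)
        log_prior += setup.fbd_param_priors.log_density(state.grid)
    state._eff = {}
    if np.isfinite(log_prior):
        for label, cs in state.clocks.items():
            eff, clock_lp = clocks.effective_lengths(tree, cs)
            state._eff[label] = eff
            log_prior += clock_lp
            if cfg.clock_model not in ("none",):
                log_prior += setup.base_rate_prior.log_density(cs.base_rate)
                if cfg.clock_model in ("igr", "tk02"):
                    rate = cfg.clock_var_prior_rate
                    if cs.variance <= 0:
                        log_prior = -np.inf
                        break
                    log_prior += math.log(rate) - rate * cs.variance
            if cfg.acrv_kind != "none":
                shape = state.acrv_shape[label]
                if shape <= 0:
                    log_prior = -np.inf
                    break
                r0 = setup.acrv_shape_prior_rate
                log_prior += math.log(r0) - r0 * shape
        if state.alpha_dir is not None:
            lo, hi = cfg.alpha_dir_bounds
            if not (lo <= state.alpha_dir <= hi):
                log_prior = -np.inf
    state.log_prior = float(log_prior)
    if not np.isfinite(log_prior):
        state.log_likelihood = -np.inf
        return -np.inf
    if likelihood_power == 0.0:
        state.log_likelihood = 0.0
        return state.log_prior
    for label, cs in state.clocks.items():
        if update_labels is None or label in update_labels \
                or label not in state._lnl_parts:
            state._lnl_parts[label] = setup.engines[label].log_likelihood(
                tree, state._eff[label], mk_spec_for(setup, state, label))
    state.log_likelihood = float(sum(state._lnl_parts.values()))
    return state.log_prior + likelihood_power * state.log_likelihood


# --------------------------------------------------------------------------
# Proposals
# --------------------------------------------------------------------------

def _scale(value: float, rng, tuning: float = 1.0) -> tuple[float, float]:
    m = math.exp(tuning * (rng.random() - 0.5))
    return value * m, math.log(m)


def _reflect(value: float, lo: float, hi: float) -> float:
    width = hi - lo
    if width <= 0:
        raise _Reject
    v = (value - lo) % (2.0 * width)
    return lo + (width - abs(v - width))


def _slideable_internals(tree: TimeTree) -> list[Node]:
    return [n for n in tree.internals()
            if n.parent is not None and not tree.sa_attachment(n)]


def move_node_age(state, setup, rng):
    nodes = _slideable_internals(state.tree)
    if not nodes:
        raise _Reject
    node = nodes[rng.integers(len(nodes))]
    lo = max(c.age for c in node.children)
    hi = node.parent.age
    if hi - lo <= 0:
        raise _Reject
    node.age = lo + rng.random() * (hi - lo)
    return 0.0


def move_root_age(state, setup, rng, window: float = 40.0):
    root = state.tree.root
    lo = max(c.age for c in root.children)
    new = root.age + (rng.random() - 0.5) * window
    if new < lo:
        new = 2.0 * lo - new
    root.age = new
    return 0.0


def move_tip_age(state, setup, rng):
    tree = state.tree
    tips = [t for t in tree.leaves() if t.age > 1e-9]
    if not tips:
        raise _Reject
    tip = tips[rng.integers(len(tips))]
    cal = setup.calibrations[tip.taxon]
    if tree.is_sampled_ancestor(tip):
        p = tip.parent
        other = [c for c in p.children if c is not tip]
        lo = max([cal.age_min] + [c.age for c in other])
        hi = min(cal.age_max, p.parent.age) if p.parent is not None else cal.age_max
        if hi - lo <= 0:
            raise _Reject
        new = lo + rng.random() * (hi - lo)
        tip.age = new
        p.age = new
    else:
        lo = cal.age_min
        hi = min(cal.age_max, tip.parent.age)
        if hi - lo <= 0:
            raise _Reject
        tip.age = lo + rng.random() * (hi - lo)
    return 0.0


def move_narrow_exchange(state, setup, rng):
    tree = state.tree
    cands = [n for n in tree.internals()
             if n.parent is not None and n.parent.parent is not None
             and not tree.sa_attachment(n.parent)
             and not tree.sa_attachment(n.parent.parent)]
    if not cands:
        raise _Reject
    p = cands[rng.integers(len(cands))].parent
    g = p.parent
    uncles = [c for c in g.children if c is not p]
    u = uncles[rng.integers(len(uncles))]
    kids = p.children
    a = kids[rng.integers(len(kids))]
    if u.age >= p.age or tree.is_sampled_ancestor(u) or tree.is_sampled_ancestor(a):
        raise _Reject
    g.children[g.children.index(u)] = a
    a.parent = g
    p.children[p.children.index(a)] = u
    u.parent = p
    return 0.0


def _spr_targets(tree: TimeTree, a: Node) -> list[Node]:
    """Edges (identified by child node) onto which subtree ``a`` may attach."""
    in_subtree = set()
    stack = [a]
    while stack:
        n = stack.pop()
        in_subtree.add(n)
        stack.extend(n.children)
    out = []
    for v in tree.preorder():
        if v in in_subtree or v.parent is None or v.parent in in_subtree:
            continue
        hi = v.parent.age
        lo = max(a.age, v.age)
        if hi > lo:
            out.append(v)
    return out


def move_spr(state, setup, rng):
    """Fixed-dimension subtree prune and regraft on the time tree; the
    pruned subtree's attachment node travels with its clock variables."""
    tree = state.tree
    cands = [n for n in tree.preorder()
             if n.parent is not None and n.parent.parent is not None
             and not tree.sa_attachment(n.parent)
             and not tree.is_sampled_ancestor(n)]
    if not cands:
        raise _Reject
    a = cands[rng.integers(len(cands))]
    p = a.parent
    g = p.parent
    o = [c for c in p.children if c is not a][0]
    lo0 = max(a.age, o.age)
    hi0 = g.age

    # detach
    g.children[g.children.index(p)] = o
    o.parent = g
    p.children = [a]

    targets = _spr_targets(tree, a)
    targets = [v for v in targets if v is not p]
    if not targets:  # restore impossible-to-move state
        raise _Reject
    v = targets[rng.integers(len(targets))]
    lo = max(a.age, v.age)
    hi = v.parent.age
    new_age = lo + rng.random() * (hi - lo)
    u = v.parent
    u.children[u.children.index(v)] = p
    p.parent = u
    p.children = [a, v]
    v.parent = p
    p.age = new_age
    n_fwd = len(targets)
    # reverse: from the new tree, detaching a again can target o's edge
    rev_targets = _spr_targets_after(tree, a, p)
    n_rev = len(rev_targets)
    if hi0 <= lo0 or n_rev == 0:
        raise _Reject
    log_fwd = -math.log(n_fwd) - math.log(hi - lo)
    log_rev = -math.log(n_rev) - math.log(hi0 - lo0)
    return log_rev - log_fwd


def _spr_targets_after(tree: TimeTree, a: Node, p: Node) -> list[Node]:
    """Candidate targets for the reverse prune of ``a`` (p currently its
    parent): same enumeration with p spliced out."""
    in_subtree = {p}
    stack = [a]
    while stack:
        n = stack.pop()
        in_subtree.add(n)
        stack.extend(n.children)
    out = []
    for v in tree.preorder():
        if v in in_subtree or v.parent is None:
            continue
        parent = v.parent
        if parent is p:
            parent = p.parent  # p will be spliced out when detaching
        if parent in in_subtree:
            continue
        hi = parent.age
        lo = max(a.age, v.age)
        if hi > lo:
            out.append(v)
    return out


def move_tree_scale(state, setup, rng, tuning: float = 0.3):
    """Multiply the root and all interior ages by a common factor, keeping
    tip ages (and sampled-ancestor attachments) fixed."""
    tree = state.tree
    m = math.exp(tuning * (rng.random() - 0.5))
    scaled = 0
    for node in tree.internals():
        if tree.sa_attachment(node):
            continue
        node.age *= m
        scaled += 1
    for node in tree.internals():
        if node.children and node.age < max(c.age for c in node.children):
            raise _Reject
    return scaled * math.log(m)


def move_rate_age_tradeoff(state, setup, rng, tuning: float = 0.4):
    """Compensatory scaling along the rate-time ridge: interior ages are
    multiplied by m while every base rate (and TK02 node rate) is divided
    by m, leaving all effective branch lengths -- and hence the likelihood
    -- unchanged."""
    tree = state.tree
    m = math.exp(tuning * (rng.random() - 0.5))
    n_ages = 0
    for node in tree.internals():
        if tree.sa_attachment(node):
            continue
        node.age *= m
        n_ages += 1
    for node in tree.internals():
        if node.children and node.age < max(c.age for c in node.children):
            raise _Reject
    n_rates = 0
    for cs in state.clocks.values():
        cs.base_rate /= m
        n_rates += 1
        if cs.model == "tk02":
            for node, r in cs.branch_values.items():
                cs.branch_values[node] = r / m
                n_rates += 1
    return (n_ages - n_rates) * math.log(m)


def move_clock_rate_rescale(state, setup, rng, tuning: float = 1.5):
    """Scale one clock's base rate together with its branch quantities, so
    relative branch rates are preserved (decorrelates c from the lengths)."""
    label = _random_label(state, rng)
    cs = state.clocks[label]
    if cs.model not in ("igr", "tk02"):
        raise _Reject
    m = math.exp(tuning * (rng.random() - 0.5))
    cs.base_rate *= m
    n = 1
    for node, v in cs.branch_values.items():
        if v > 0:
            cs.branch_values[node] = v * m
            n += 1
    return n * math.log(m)


def move_scale_base_rate(state, setup, rng):
    label = _random_label(state, rng)
    cs = state.clocks[label]
    cs.base_rate, logm = _scale(cs.base_rate, rng)
    return logm


def move_scale_clock_var(state, setup, rng):
    label = _random_label(state, rng)
    cs = state.clocks[label]
    cs.variance, logm = _scale(cs.variance, rng)
    return logm


def move_scale_acrv(state, setup, rng):
    label = _random_label(state, rng)
    state.acrv_shape[label], logm = _scale(state.acrv_shape[label], rng)
    return logm


def move_alpha_dir(state, setup, rng, window: float = 2.0):
    lo, hi = setup.config.alpha_dir_bounds
    state.alpha_dir = _reflect(state.alpha_dir + (rng.random() - 0.5) * window, lo, hi)
    return 0.0


def move_branch_value(state, setup, rng):
    label = _random_label(state, rng)
    cs = state.clocks[label]
    tree = state.tree
    nodes = [n for n in tree.preorder()
             if n.parent is not None and tree.duration(n) > 1e-9]
    if not nodes or cs.model == "strict":
        raise _Reject
    node = nodes[rng.integers(len(nodes))]
    cur = cs.branch_values.get(node)
    if cur is None or cur <= 0:
        raise _Reject
    cs.branch_values[node], logm = _scale(cur, rng)
    return logm


def move_igr_variance_rescale(state, setup, rng, tuning: float = 1.2):
    """Joint update of the IGR variance and the branch-length residuals:
    nu is scaled by m and each effective length's log-residual around its
    strict-clock mean by sqrt(m), so the relative dispersion tracks the new
    variance (a ridge move along the nu <-> spread direction)."""
    label = _random_label(state, rng)
    cs = state.clocks[label]
    if cs.model != "igr":
        raise _Reject
    m = math.exp(tuning * (rng.random() - 0.5))
    alpha = math.sqrt(m)
    cs.variance *= m
    log_jac = math.log(m)  # d(nu')/d(nu)
    tree = state.tree
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = tree.duration(node)
        v = cs.branch_values.get(node, 0.0)
        if t <= 1e-9 or v <= 0:
            continue
        mean = cs.base_rate * t
        new = mean * (v / mean) ** alpha
        log_jac += math.log(alpha) + (alpha - 1.0) * (math.log(v) - math.log(mean))
        cs.branch_values[node] = new
    return log_jac


def move_branch_redraw(state, setup, rng):
    """Independence proposal: redraw one clock's branch quantities from
    their prior given the current base rate and variance.  The Hastings
    term cancels the prior ratio, so under prior-only sampling this is an
    exact Gibbs update; under the posterior it is accepted on the
    likelihood ratio."""
    label = _random_label(state, rng)
    cs = state.clocks[label]
    if cs.model not in ("igr", "tk02", "none"):
        raise _Reject
    _, lp_old = clocks.effective_lengths(state.tree, cs)
    cs.branch_values = {}
    _, lp_new = clocks.effective_lengths(state.tree, cs, rng)
    if not (np.isfinite(lp_old) and np.isfinite(lp_new)):
        raise _Reject
    return lp_old - lp_new


def move_fbd_d(state, setup, rng):
    logm_total = 0.0
    if state.grid.free_mask == "s":
        new, logm = _scale(state.grid.slices[0].d, rng)
        for p in state.grid.slices:
            p.d = new
        logm_total = logm
    else:
        i = rng.integers(len(state.grid.slices))
        state.grid.slices[i].d, logm_total = _scale(state.grid.slices[i].d, rng)
    return logm_total


def move_fbd_r(state, setup, rng, window: float = 0.2):
    if state.grid.free_mask == "s":
        new = _reflect(state.grid.slices[0].r + (rng.random() - 0.5) * window, 0.0, 1.0 - 1e-9)
        for p in state.grid.slices:
            p.r = new
    else:
        i = rng.integers(len(state.grid.slices))
        p = state.grid.slices[i]
        p.r = _reflect(p.r + (rng.random() - 0.5) * window, 0.0, 1.0 - 1e-9)
    return 0.0


def move_fbd_s(state, setup, rng, window: float = 0.2):
    i = rng.integers(len(state.grid.slices))
    p = state.grid.slices[i]
    p.s = _reflect(p.s + (rng.random() - 0.5) * window, 0.0, 1.0 - 1e-9)
    return 0.0


# ---- reversible-jump sampled-ancestor pair --------------------------------

def _sa_tips(tree: TimeTree) -> list[Node]:
    return [t for t in tree.leaves() if tree.is_sampled_ancestor(t)
            and t.parent.parent is not None]


def _delete_candidates(tree: TimeTree) -> list[Node]:
    out = []
    for t in tree.leaves():
        if t.age <= 1e-9 or tree.is_sampled_ancestor(t):
            continue
        p = t.parent
        if p is None or p.parent is None:
            continue
        other = [c for c in p.children if c is not t][0]
        if other.age < t.age < p.parent.age:
            out.append(t)
    return out


def _rj_aux_log_density(state: ChainState, setup: ModelSetup, tip: Node,
                        draw: bool, rng) -> float:
    """Log prior density of the branch-specific clock variables on the
    fossil tip's edge; with ``draw`` they are freshly sampled from that
    prior (reversible-jump auxiliary variables)."""
    total = 0.0
    tree = state.tree
    t = tree.duration(tip)
    for label, cs in state.clocks.items():
        if cs.model == "igr":
            if draw:
                cs.branch_values[tip] = clocks.sample_igr_branch(
                    t, cs.base_rate, cs.variance, rng)
            total += clocks.igr_branch_log_prior(
                t, cs.base_rate, cs.variance, cs.branch_values.get(tip, 0.0))
        elif cs.model == "tk02":
            parent_rate = cs.branch_values.get(tip.parent, cs.base_rate)
            if tip.parent.parent is None:
                parent_rate = cs.base_rate
            if draw:
                cs.branch_values[tip] = clocks.sample_tk02_rate(
                    parent_rate, cs.variance, t, rng)
            total += clocks.tk02_node_log_prior(
                cs.branch_values.get(tip, parent_rate), parent_rate,
                cs.variance, t)
    return total


def move_sa_add(state, setup, rng):
    """Sampled ancestor -> fossil tip (AddBranch): unpin the attachment age."""
    tree = state.tree
    sas = _sa_tips(tree)
    if not sas:
        raise _Reject
    tip = sas[rng.integers(len(sas))]
    p = tip.parent
    g = p.parent
    lo, hi = tip.age, g.age
    if hi <= lo:
        raise _Reject
    p.age = lo + rng.random() * (hi - lo)
    aux = _rj_aux_log_density(state, setup, tip, draw=True, rng=rng)
    n_del_after = len(_delete_candidates(tree))
    if n_del_after == 0:
        raise _Reject
    log_fwd = -math.log(len(sas)) - math.log(hi - lo) + aux
    log_rev = -math.log(n_del_after)
    return log_rev - log_fwd


def move_sa_delete(state, setup, rng):
    """Fossil tip -> sampled ancestor (DelBranch): pin the attachment age to
    the fossil age and drop the edge's clock variables."""
    tree = state.tree
    cands = _delete_candidates(tree)
    if not cands:
        raise _Reject
    tip = cands[rng.integers(len(cands))]
    p = tip.parent
    g = p.parent
    lo, hi = tip.age, g.age
    aux = _rj_aux_log_density(state, setup, tip, draw=False, rng=rng)
    p.age = tip.age
    for cs in state.clocks.values():
        if cs.model == "igr":
            cs.branch_values[tip] = 0.0
        elif cs.model == "tk02":
            cs.branch_values[tip] = cs.branch_values.get(p, cs.base_rate)
    n_sa_after = len(_sa_tips(tree))
    log_fwd = -math.log(len(cands))
    log_rev = -math.log(n_sa_after) - math.log(hi - lo) + aux
    return log_rev - log_fwd


def _random_label(state: ChainState, rng) -> str:
    labels = list(state.clocks)
    label = labels[rng.integers(len(labels))]
    state._touched = label
    return label


# Which partitions' likelihoods a move can change.  FBD parameters never
# enter the likelihood; under the IGR clock the effective lengths are free
# parameters, so age-only moves and the base-rate/variance scalers leave the
# likelihood untouched as well.
_AGE_MOVES = {"node_age", "root_age", "tree_scale", "tip_age"}
_LABEL_MOVES = {"branch_value", "branch_redraw", "clock_rescale",
                "igr_var_rescale", "acrv_shape", "base_rate", "clock_var"}


def _labels_to_update(name: str, state: ChainState, setup: ModelSetup):
    model = setup.config.clock_model
    if name in _PRIOR_ONLY_MOVES or name == "clock_var":
        return set()
    if name == "rate_age_tradeoff":
        return set()  # effective lengths are invariant by construction
    if name in _AGE_MOVES:
        return set() if model in ("igr", "none") else None
    if name in _LABEL_MOVES:
        if name == "base_rate" and model in ("igr", "none"):
            return set()
        return {state._touched}
    return None  # topology and everything else: recompute all


# --------------------------------------------------------------------------
# Move schedule
# --------------------------------------------------------------------------

@dataclass
class MoveSet:
    moves: list[tuple[str, float, Callable]]

    def __post_init__(self):
        if not self.moves or all(w <= 0 for _, w, _ in self.moves):
            raise ValueError("move set has no positive weights")

    def pick(self, rng):
        weights = np.array([w for _, w, _ in self.moves])
        idx = rng.choice(len(self.moves), p=weights / weights.sum())
        return self.moves[idx]


def default_move_set(setup: ModelSetup) -> MoveSet:
    cfg = setup.config
    has_fossils = len(setup.calibrations.fossil_taxa()) > 0
    moves: list[tuple[str, float, Callable]] = []

    def add(name, weight, fn):
        weight = cfg.move_weights.get(name, weight)
        if weight > 0:
            moves.append((name, weight, fn))

    clocked = cfg.clock_model != "none"
    add("node_age", 3.0 if clocked else 0.0, move_node_age)
    add("root_age", 1.0 if clocked else 0.0, move_root_age)
    add("tree_scale", 1.0 if clocked else 0.0, move_tree_scale)
    if clocked and not cfg.fix_clock_rate:
        add("rate_age_tradeoff", 1.5, move_rate_age_tradeoff)
    add("tip_age", 2.0 if (has_fossils and clocked) else 0.0, move_tip_age)
    if not cfg.fix_topology:
        add("narrow_exchange", 2.0, move_narrow_exchange)
        add("spr", 1.0, move_spr)
    if not cfg.fix_clock_rate and clocked:
        add("base_rate", 1.5, move_scale_base_rate)
        if cfg.clock_model in ("igr", "tk02"):
            add("clock_rescale", 1.5, move_clock_rate_rescale)
    if cfg.clock_model in ("igr", "tk02"):
        add("clock_var", 1.0, move_scale_clock_var)
    if cfg.clock_model == "igr":
        add("igr_var_rescale", 1.0, move_igr_variance_rescale)
    if cfg.clock_model in ("igr", "tk02", "none"):
        add("branch_value", 3.0, move_branch_value)
        add("branch_redraw", 0.5, move_branch_redraw)
    if cfg.acrv_kind != "none":
        add("acrv_shape", 1.0, move_scale_acrv)
    if cfg.freq_model == "asymmetric":
        add("alpha_dir", 1.0, move_alpha_dir)
    if clocked:
        add("fbd_d", 1.0, move_fbd_d)
        add("fbd_r", 1.0, move_fbd_r)
        add("fbd_s", 1.0, move_fbd_s)
    sa_ok = cfg.sampled_ancestors_allowed and has_fossils and not cfg.fix_topology
    add("sa_add", 1.0 if sa_ok else 0.0, move_sa_add)
    add("sa_delete", 1.0 if sa_ok else 0.0, move_sa_delete)
    return MoveSet(moves)


# --------------------------------------------------------------------------
# Samples and the sampler
# --------------------------------------------------------------------------

_PRIOR_ONLY_MOVES = {"fbd_d", "fbd_r", "fbd_s"}


@dataclass
class PosteriorSample:
    generation: int
    run_id: int
    tree: TimeTree
    scalars: dict[str, float]
    log_likelihood: float
    log_prior: float


def _initial_state(setup: ModelSetup, rng) -> ChainState:
    cfg = setup.config
    cal = setup.calibrations
    tip_ages = {}
    for taxon in setup.matrix.taxon_names:
        c = cal[taxon]
        tip_ages[taxon] = 0.0 if c.is_extant else 0.5 * (c.age_min + c.age_max)
    max_tip = max(tip_ages.values())
    if cfg.starting_tree:
        tree = TimeTree.from_newick(cfg.starting_tree, tip_ages=tip_ages)
        # snap tip ages into their calibration ranges (branch lengths in the
        # supplied tree need not match the calibration midpoints)
        for leaf in tree.leaves():
            c = cal[leaf.taxon]
            leaf.age = 0.0 if c.is_extant else min(max(leaf.age, c.age_min),
                                                   c.age_max)
        for node in tree.postorder():
            if node.children:
                # keep speciation nodes strictly above their children so no
                # accidental sampled-ancestor configurations arise
                node.age = max(node.age, max(c.age for c in node.children) + 0.1)
        if tree.root.age <= max_tip:
            tree.root.age = max_tip * 1.2
    else:
        for _ in range(100):
            root_age = setup.root_cal.sample(rng)
            if root_age > max_tip * 1.05:
                break
        else:
            root_age = max_tip * 1.5
        tree = random_calibrated_tree(tip_ages, root_age, rng)
    if setup.strategy.diversified:
        xc = setup.strategy.x_cut
        for node in tree.internals():
            if node.age < xc:
                node.age = xc + rng.random() * max(tree.root.age - xc, 1.0) * 0.05
        _repair_ages(tree)

    n_slices = len(cfg.shift_times) + 1
    d0 = 1.0 / cfg.diversification_prior_rate
    slices = [fbd.FBDParams(d=d0, r=0.5, s=0.2, rho=cfg.rho) for _ in range(n_slices)]
    grid = fbd.SkylineGrid(tuple(cfg.shift_times), slices, cfg.skyline_mask, cfg.x_cut)

    clock_states = {}
    acrv_shape = {}
    labels = list(setup.partitions)
    for label in labels:
        c0 = setup.base_rate_prior.mean
        var0 = 0.5 / cfg.clock_var_prior_rate
        cs = clocks.ClockState(cfg.clock_model, c0,
                               var0 if cfg.clock_model in ("igr", "tk02")
                               else (cfg.clock_var_prior_rate
                                     if cfg.clock_model == "none" else 0.0))
        if cfg.clock_model == "none":
            cs.variance = 10.0  # exponential rate for free branch lengths
        clocks.effective_lengths(tree, cs, rng)  # populate branch values
        clock_states[label] = cs
        acrv_shape[label] = 1.0
    alpha_dir = None
    if cfg.freq_model == "asymmetric":
        alpha_dir = 0.5 * sum(cfg.alpha_dir_bounds)
    return ChainState(tree, clock_states, acrv_shape, alpha_dir, grid)


def _repair_ages(tree: TimeTree) -> None:
    for node in tree.postorder():
        if node.children:
            top = max(c.age for c in node.children)
            if node.age < top:
                node.age = top


def run_single_chain(setup: ModelSetup, rng, n_generations: int,
                     sample_interval: int, run_id: int = 0,
                     likelihood_power: float = 1.0,
                     initial_state: Optional[ChainState] = None,
                     move_set: Optional[MoveSet] = None
                     ) -> tuple[list[PosteriorSample], dict, ChainState]:
    """One Metropolis-Hastings chain; returns (samples, acceptance, state)."""
    moves = move_set or default_move_set(setup)
    state = initial_state.copy() if initial_state is not None else None
    if state is None:
        for attempt in range(100):
            state = _initial_state(setup, rng)
            if np.isfinite(evaluate(state, setup, likelihood_power)):
                break
        else:
            raise RuntimeError("could not find a finite starting state")
    log_post = evaluate(state, setup, likelihood_power)
    if not np.isfinite(log_post):
        raise RuntimeError("initial state has log posterior -inf")

    accepted = {name: 0 for name, _, _ in moves.moves}
    attempted = {name: 0 for name, _, _ in moves.moves}
    samples: list[PosteriorSample] = []
    for gen in range(1, n_generations + 1):
        name, _, fn = moves.pick(rng)
        attempted[name] += 1
        cand = state.copy()
        try:
            log_hastings = fn(cand, setup, rng)
            cand_post = evaluate(cand, setup, likelihood_power,
                                 update_labels=_labels_to_update(name, cand, setup))
        except _Reject:
            cand_post = -np.inf
            log_hastings = 0.0
        if np.isfinite(cand_post):
            log_alpha = cand_post - log_post + log_hastings
            if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
                state = cand
                log_post = cand_post
                accepted[name] += 1
        if gen % sample_interval == 0:
            samples.append(_record(state, setup, gen, run_id))
    acceptance = {
        name: (accepted[name] / attempted[name] if attempted[name] else np.nan)
        for name in attempted
    }
    return samples, acceptance, state


def _record(state: ChainState, setup: ModelSetup, gen: int, run_id: int) -> PosteriorSample:
    tree = state.tree.copy()
    node_pairs = list(zip(state.tree.preorder(), tree.preorder()))
    scalars = {
        "generation": gen,
        "lnL": state.log_likelihood,
        "lnPrior": state.log_prior,
        "root_age": state.tree.root.age,
        "n_sa": float(len(state.tree.sampled_ancestors())),
        "tree_length": sum(state.tree.duration(n) for n in state.tree.preorder()
                           if n.parent is not None),
    }
    for label, cs in state.clocks.items():
        scalars[f"clock_rate_{label}"] = cs.base_rate
        scalars[f"clock_var_{label}"] = cs.variance
        scalars[f"acrv_shape_{label}"] = state.acrv_shape[label]
        eff = state._eff.get(label, {})
        for old, new in node_pairs:
            if old.parent is None:
                continue
            t = state.tree.duration(old)
            if t > 1e-9 and old in eff:
                rel = eff[old] / (cs.base_rate * t)
            else:
                rel = 1.0
            new.meta[f"rel_rate_{label}"] = rel
    if state.alpha_dir is not None:
        scalars["alpha_dir"] = state.alpha_dir
    for i, p in enumerate(state.grid.slices):
        scalars[f"d_{i}"] = p.d
        scalars[f"r_{i}"] = p.r
        scalars[f"s_{i}"] = p.s
    return PosteriorSample(gen, run_id, tree, scalars,
                           state.log_likelihood, state.log_prior)


def run_mcmc(config: RunConfig, matrix: CharacterMatrix,
             calibrations: CalibrationTable,
             likelihood_power: float = 1.0) -> dict:
    """Run ``config.n_runs`` independent chains; returns samples, traces,
    acceptance rates and convergence diagnostics.

    The burn-in fraction is discarded from the returned post-burn-in sample
    lists (raw samples are also kept).  ``likelihood_power=0`` samples the
    joint prior.
    """
    setup = ModelSetup.build(config, matrix, calibrations)
    runs = []
    for run_id in range(config.n_runs):
        rng = np.random.default_rng([config.seed, run_id])
        samples, acceptance, state = run_single_chain(
            setup, rng, config.n_generations, config.sample_interval,
            run_id=run_id, likelihood_power=likelihood_power)
        runs.append({"samples": samples, "acceptance": acceptance,
                     "final_state": state})
    burn = config.burn_in
    post = []
    for run in runs:
        n = len(run["samples"])
        run["post_burnin"] = run["samples"][int(burn * n):]
        post.append(run["post_burnin"])
    result = {
        "setup": setup,
        "runs": runs,
        "post_burnin": post,
    }
    if config.n_runs >= 2:
        result["diagnostics"] = diagnostics_from_runs(post)
    return result


# --------------------------------------------------------------------------
# Convergence diagnostics
# --------------------------------------------------------------------------

def _splits_of(tree: TimeTree) -> set[frozenset]:
    taxa = frozenset(t.taxon for t in tree.leaves())
    out = set()
    for node, clade in tree.clades().items():
        if node.parent is None or len(clade) < 2 or clade == taxa:
            continue
        out.add(clade)
    return out


def compute_asdsf(tree_samples_per_run: list[list[TimeTree]],
                  min_freq: float = 0.1) -> float:
    """Average across-run standard deviation of split frequencies, over
    splits reaching ``min_freq`` in at least one run."""
    if len(tree_samples_per_run) < 2:
        raise ValueError("ASDSF needs at least two runs")
    freqs: list[dict[frozenset, float]] = []
    all_splits: set[frozenset] = set()
    for trees in tree_samples_per_run:
        if not trees:
            raise ValueError("empty tree sample")
        counts: dict[frozenset, int] = {}
        for t in trees:
            for s in _splits_of(t):
                counts[s] = counts.get(s, 0) + 1
        f = {s: c / len(trees) for s, c in counts.items()}
        freqs.append(f)
        all_splits |= set(f)
    sds = []
    for s in all_splits:
        vals = [f.get(s, 0.0) for f in freqs]
        if max(vals) < min_freq:
            continue
        sds.append(float(np.std(vals)))
    return float(np.mean(sds)) if sds else 0.0


def compute_psrf(traces: list[np.ndarray]) -> float:
    """Gelman-Rubin potential scale reduction factor."""
    if len(traces) < 2:
        raise ValueError("PSRF needs at least two runs")
    n = min(len(t) for t in traces)
    arr = np.array([np.asarray(t)[:n] for t in traces], dtype=float)
    within = arr.var(axis=1, ddof=1).mean()
    if within <= 0:
        return 1.0
    between = n * arr.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * within + between / n
    return float(math.sqrt(var_hat / within))


def compute_ess(trace: np.ndarray) -> float:
    """Effective sample size via the initial positive autocorrelation
    sequence (Geyer)."""
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) <= 0:
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 2
    return float(min(n, n / tau))


def compute_psrf_ess(traces_per_run: dict[str, list[np.ndarray]]) -> dict:
    """PSRF and pooled ESS per named parameter trace."""
    out = {}
    for name, traces in traces_per_run.items():
        psrf = compute_psrf(traces) if len(traces) >= 2 else np.nan
        ess = float(sum(compute_ess(t) for t in traces))
        out[name] = {"psrf": psrf, "ess": ess}
    return out


def diagnostics_from_runs(post_burnin: list[list[PosteriorSample]],
                          min_freq: float = 0.1) -> dict:
    trees = [[s.tree for s in run] for run in post_burnin]
    keys = [k for k in post_burnin[0][0].scalars
            if k not in ("generation",)]
    traces = {
        k: [np.array([s.scalars[k] for s in run]) for run in post_burnin]
        for k in keys
    }
    return {
        "asdsf": compute_asdsf(trees, min_freq=min_freq),
        "per_parameter": compute_psrf_ess(traces),
    }
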