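"""Forward simulation of study-shaped inputs.

A complete birth-death tree is grown forward in time from the root age with
speciation rate ``lambda``, extinction rate ``mu`` and Poisson fossilization
rate ``psi`` (piecewise constant under a skyline grid).  Extant taxa are
sampled either randomly (probability ``rho``) or in the diversified scheme
(one representative per lineage crossing the cutoff ``x_cut``; no fossils
younger than the cutoff).  Unsampled lineages are pruned; a fossil with
sampled descendants becomes a sampled ancestor (zero-duration tip) unless
conversion to plain tips is requested.

Characters then evolve along the sampled tree under the Mk process with
among-character rate variation and a configurable true clock; constant
characters are rejected (variable-only ascertainment) and the fraction of
direct autapomorphies is steered toward a target by rejection, never by
editing simulated states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import clocks
from .fbd import FBDParams, SkylineGrid
from .io_formats import (Calibration, CalibrationTable, CharacterMatrix,
                         RunConfig, write_calibrations, write_nexus_matrix)
from .likelihood import MkModelSpec, mk_transition_probability
from .treedata import Node, TimeTree


@dataclass
class SimulationSpec:
    """True generating conditions for one synthetic study bundle."""

    grid: SkylineGrid
    root_age: float = 270.0
    x_cut: float = 0.0
    extant_strategy: str = "random"       # random | diversified
    n_characters: dict[str, int] = field(
        default_factory=lambda: {"skull": 47, "mandible": 44, "postcranial": 38})
    state_count_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.75, 3: 0.17, 4: 0.05, 5: 0.03})
    clock_model: str = "strict"           # strict | igr | tk02
    base_rates: dict[str, float] = field(default_factory=lambda: {
        "skull": 0.02, "mandible": 0.02, "postcranial": 0.02})
    clock_variance: float = 0.0
    acrv: MkModelSpec = field(default_factory=lambda: MkModelSpec(acrv_kind="gamma",
                                                                  acrv_shape=1.0))
    rate_groups: Optional[dict[str, str]] = None
    # partitions mapped to the same group share one draw of branch rates
    # (models full integration between anatomical regions)
    autapomorphy_target: Optional[float] = 0.17
    autapomorphy_tolerance: float = 0.05
    fossil_range_width: tuple[float, float] = (2.0, 10.0)
    keep_sampled_ancestors: bool = True
    min_tips: int = 4
    max_tips: int = 200
    retry_cap: int = 500

    def __post_init__(self):
        if self.extant_strategy not in ("random", "diversified"):
            raise ValueError("extant_strategy must be 'random' or 'diversified'")
        if self.extant_strategy == "diversified" and self.x_cut <= 0:
            raise ValueError("diversified sampling needs x_cut > 0")
        total = sum(self.state_count_probs.values())
        self.state_count_probs = {k: v / total for k, v in self.state_count_probs.items()}


# --------------------------------------------------------------------------
# Tree simulation
# --------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("birth", "death", "children", "fossils", "extant", "sampled_extant")

    def __init__(self, birth: float):
        self.birth = birth          # age at which the lineage starts (old end)
        self.death: float = 0.0     # age at which it ends (young end)
        self.children: list[_Lineage] = []
        self.fossils: list[float] = []
        self.extant = False
        self.sampled_extant = False


def _rates_at(grid: SkylineGrid, age: float) -> tuple[float, float, float]:
    return grid.slices[grid.slice_index(age)].canonical()


def _next_boundary(grid: SkylineGrid, age: float) -> float:
    for t in grid.shift_times:
        if t < age - 1e-12:
            return t
    return 0.0


def _grow(lineage: _Lineage, grid: SkylineGrid, psi_cut: float, rng,
          budget: list[int]) -> None:
    """Evolve one lineage from its birth age toward the present."""
    t = lineage.birth
    while True:
        if budget[0] <= 0:
            raise RuntimeError("simulation budget exhausted")
        lam, mu, psi = _rates_at(grid, t)
        if t <= psi_cut:
            psi = 0.0
        total = lam + mu + psi
        boundary = max(_next_boundary(grid, t), psi_cut if t > psi_cut else 0.0)
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if t - wait <= boundary:
            if boundary <= 1e-12:
                lineage.death = 0.0
                lineage.extant = True
                return
            t = boundary - 1e-9  # step just past the shift time
            continue
        t -= wait
        u = rng.random() * total
        if u < lam:
            budget[0] -= 2
            lineage.death = t
            for _ in range(2):
                child = _Lineage(t)
                lineage.children.append(child)
                _grow(child, grid, psi_cut, rng, budget)
            return
        if u < lam + mu:
            lineage.death = t
            return
        budget[0] -= 1
        lineage.fossils.append(t)


def _prune(lineage: _Lineage, spec: SimulationSpec, names: dict, rng) -> Optional[Node]:
    """Reduce a full lineage to its sampled subtree (None when unsampled)."""
    if lineage.children:
        reduced = [node for c in lineage.children
                   if (node := _prune(c, spec, names, rng)) is not None]
        if len(reduced) == 2:
            base = Node(lineage.death)
            for r in reduced:
                base.add_child(r)
        elif len(reduced) == 1:
            base = reduced[0]
        else:
            base = None
    else:
        base = None
        if lineage.sampled_extant:
            names["extant"] += 1
            base = Node(0.0, taxon=f"extant_{names['extant']}")
    for age in sorted(lineage.fossils):
        names["fossil"] += 1
        tip = Node(age, taxon=f"fossil_{names['fossil']}")
        if base is None:
            base = tip
        else:
            attach_age = age
            if not spec.keep_sampled_ancestors:
                ceiling = lineage.birth
                attach_age = age + (ceiling - age) * rng.beta(1.0, 9.0)
            attach = Node(attach_age)
            attach.add_child(base)
            attach.add_child(tip)
            base = attach
    return base


def _mark_extant_samples(root_lineages: list[_Lineage], spec: SimulationSpec, rng) -> int:
    rho = spec.grid.slices[0].rho
    if spec.extant_strategy == "random":
        n = 0
        for lin in _iter_lineages(root_lineages):
            if lin.extant and rng.random() < rho:
                lin.sampled_extant = True
                n += 1
        return n
    # diversified: one representative per lineage crossing x_cut with
    # surviving descendants
    n = 0
    for crossing in _lineages_crossing(root_lineages, spec.x_cut):
        extant = [l for l in _iter_lineages([crossing]) if l.extant]
        if extant:
            rng.choice(extant).sampled_extant = True
            n += 1
    return n


def _iter_lineages(roots):
    stack = list(roots)
    while stack:
        lin = stack.pop()
        yield lin
        stack.extend(lin.children)


def _lineages_crossing(roots, age):
    for lin in _iter_lineages(roots):
        if lin.birth >= age and (lin.death < age or (lin.extant and age > 0)):
            yield lin


def simulate_fbd_tree(spec: SimulationSpec, rng) -> tuple[TimeTree, CalibrationTable]:
    """Simulate a sampled FBD tree plus its tip-calibration table."""
    psi_cut = spec.x_cut if spec.extant_strategy == "diversified" else 0.0
    for _ in range(spec.retry_cap):
        roots = [_Lineage(spec.root_age), _Lineage(spec.root_age)]
        try:
            budget = [8 * spec.max_tips]
            for lin in roots:
                _grow(lin, spec.grid, psi_cut, rng, budget)
        except RuntimeError:
            continue
        n_extant = _mark_extant_samples(roots, spec, rng)
        names = {"extant": 0, "fossil": 0}
        sides = [_prune(lin, spec, names, rng) for lin in roots]
        if any(s is None for s in sides):
            continue
        root = Node(spec.root_age)
        for s in sides:
            root.add_child(s)
        tree = TimeTree(root)
        tips = tree.leaves()
        if not (spec.min_tips <= len(tips) <= spec.max_tips) or n_extant < 1:
            continue
        tree.validate()
        calibrations = _make_calibrations(tree, spec, rng)
        return tree, calibrations
    raise RuntimeError("no acceptable tree after retry cap; adjust rates or caps")


def _make_calibrations(tree: TimeTree, spec: SimulationSpec, rng) -> CalibrationTable:
    entries = {}
    lo_w, hi_w = spec.fossil_range_width
    for tip in tree.leaves():
        if tip.age <= 1e-9:
            entries[tip.taxon] = Calibration(0.0, 0.0)
        else:
            width = rng.uniform(lo_w, hi_w)
            u = rng.random()
            age_min = max(tip.age - u * width, 0.0)
            entries[tip.taxon] = Calibration(age_min, age_min + width)
    return CalibrationTable(entries)


# --------------------------------------------------------------------------
# Matrix simulation
# --------------------------------------------------------------------------

def _true_effective_lengths(tree: TimeTree, spec: SimulationSpec, label: str,
                            rng) -> dict[Node, float]:
    state = clocks.ClockState(spec.clock_model, spec.base_rates[label],
                              spec.clock_variance)
    eff, _ = clocks.effective_lengths(tree, state, rng)
    return eff


def _draw_acrv_rate(spec: MkModelSpec, rng) -> float:
    if spec.acrv_kind == "none":
        return 1.0
    if spec.acrv_kind == "gamma":
        a = spec.acrv_shape
        return float(rng.gamma(a, 1.0 / a))
    sigma = spec.acrv_shape
    return float(np.exp(-0.5 * sigma ** 2 + sigma * rng.standard_normal()))


def _simulate_character(tree: TimeTree, eff: dict[Node, float], k: int,
                        rate: float, rng) -> dict[str, int]:
    states: dict[Node, int] = {tree.root: int(rng.integers(k))}
    for node in tree.preorder():
        if node.parent is None:
            continue
        P = mk_transition_probability(k, rate * eff[node])
        states[node] = int(rng.choice(k, p=P[states[node.parent]]))
    return {n.taxon: states[n] for n in tree.leaves()}


def _classify_column(values: list[int]) -> tuple[bool, bool]:
    """(is_variable, is_direct_autapomorphy) for a fully observed column."""
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    if len(counts) < 2:
        return False, False
    n = len(values)
    return True, max(counts.values()) == n - 1


def simulate_matrix(tree: TimeTree, spec: SimulationSpec, rng) -> CharacterMatrix:
    """Simulate a partitioned matrix of variable characters on ``tree``."""
    taxa = [n.taxon for n in tree.leaves()]
    ks = sorted(spec.state_count_probs)
    kp = np.array([spec.state_count_probs[k] for k in ks])
    target = spec.autapomorphy_target
    n_total = sum(spec.n_characters.values())
    if target is not None:
        lo = max(int(np.ceil((target - spec.autapomorphy_tolerance) * n_total)), 0)
        hi = int(np.floor((target + spec.autapomorphy_tolerance) * n_total))
    columns: list[list[int]] = []
    counts: list[int] = []
    labels: list[str] = []
    n_aut = 0
    group_eff: dict[str, dict] = {}
    for label, n_chars in spec.n_characters.items():
        group = (spec.rate_groups or {}).get(label, label)
        if group not in group_eff:
            group_eff[group] = _true_effective_lengths(tree, spec, label, rng)
        eff = group_eff[group]
        produced = 0
        while produced < n_chars:
            for attempt in range(spec.retry_cap):
                k = int(rng.choice(ks, p=kp))
                rate = _draw_acrv_rate(spec.acrv, rng)
                col = _simulate_character(tree, eff, k, rate, rng)
                values = [col[t] for t in taxa]
                variable, aut = _classify_column(values)
                if not variable:
                    continue
                if target is not None:
                    slots_left = n_total - len(columns) - 1
                    if aut and n_aut + 1 > hi:
                        continue
                    if not aut and n_aut + slots_left < lo:
                        continue
                break
            else:
                raise RuntimeError(
                    "could not draw an acceptable character; zero branch "
                    "lengths or unattainable autapomorphy target")
            observed = sorted(set(values))
            recode = {s: i for i, s in enumerate(observed)}
            columns.append([recode[v] for v in values])
            counts.append(max(len(observed), 2))
            labels.append(label)
            n_aut += aut
            produced += 1
    cells = [[columns[j][i] for j in range(len(columns))] for i in range(len(taxa))]
    return CharacterMatrix(list(taxa), cells, counts, labels)


# --------------------------------------------------------------------------
# Study bundle
# --------------------------------------------------------------------------

def study_spec(seed_scale: str = "full") -> SimulationSpec:
    """Default study-shaped conditions: a mostly extinct clade sampled from
    the Triassic onward with a single living representative, three anatomical
    partitions and ~17% direct autapomorphies.

    ``seed_scale='desk'`` shrinks taxon and character counts for fast
    closed-loop testing while keeping the same structure.
    """
    grid = SkylineGrid(
        shift_times=(145.0,),
        slices=[
            FBDParams(d=0.02, r=0.5, s=0.45, rho=1.0),
            FBDParams(d=0.02, r=0.5, s=0.15, rho=1.0),
        ],
        free_mask="s",
        x_cut=66.0,
    )
    spec = SimulationSpec(
        grid=grid,
        root_age=270.0,
        x_cut=66.0,
        extant_strategy="diversified",
        clock_model="igr",
        clock_variance=0.005,
        # ~2-4 expected changes per character over the whole tree, the
        # regime that yields study-like homoplasy and autapomorphy levels
        base_rates={"skull": 0.005, "mandible": 0.005, "postcranial": 0.005},
        acrv=MkModelSpec(acrv_kind="gamma", acrv_shape=0.5),
        n_characters={"skull": 47, "mandible": 44, "postcranial": 38},
        min_tips=25,
        max_tips=45,
    )
    if seed_scale == "desk":
        spec.n_characters = {"skull": 22, "mandible": 20, "postcranial": 18}
        spec.min_tips = 10
        spec.max_tips = 30
        spec.root_age = 150.0
        spec.grid = SkylineGrid(
            shift_times=(100.0,),
            slices=[
                FBDParams(d=0.03, r=0.5, s=0.5, rho=1.0),
                FBDParams(d=0.03, r=0.5, s=0.2, rho=1.0),
            ],
            free_mask="s",
            x_cut=50.0,
        )
        spec.x_cut = 50.0
    return spec


def make_study_bundle(spec: SimulationSpec, outdir: str, seed: int = 1) -> dict:
    """Write matrix/calibration/config files plus a truth sidecar; returns
    the paths and in-memory objects."""
    import os

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    tree, calibrations = simulate_fbd_tree(spec, rng)
    matrix = simulate_matrix(tree, spec, rng)

    matrix_path = os.path.join(outdir, "matrix.nex")
    cal_path = os.path.join(outdir, "calibrations.csv")
    config_path = os.path.join(outdir, "config.yaml")
    truth_path = os.path.join(outdir, "truth.json")

    write_nexus_matrix(matrix, matrix_path)
    write_calibrations(calibrations, cal_path)
    config = RunConfig(
        clock_model=spec.clock_model if spec.clock_model != "strict" else "igr",
        sampling_strategy=("nosa_diversity" if spec.extant_strategy == "diversified"
                           else "fossiltip"),
        x_cut=spec.x_cut,
        shift_times=tuple(spec.grid.shift_times),
        skyline_mask=spec.grid.free_mask,
        seed=seed,
    )
    config.to_yaml(config_path)
    truth = {
        "seed": seed,
        "root_age": tree.root.age,
        "n_taxa": len(tree.leaves()),
        "n_extant": tree.n_extant(),
        "n_characters": matrix.n_characters,
        "autapomorphy_fraction": matrix.autapomorphy_fraction(),
        "base_rates": spec.base_rates,
        "clock_model": spec.clock_model,
        "clock_variance": spec.clock_variance,
        "fbd_slices": [
            {"d": p.d, "r": p.r, "s": p.s, "rho": p.rho} for p in spec.grid.slices
        ],
        "shift_times": list(spec.grid.shift_times),
        "newick": tree.to_newick(),
    }
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2)
    return {
        "matrix": matrix, "calibrations": calibrations, "tree": tree,
        "config": config, "paths": {
            "matrix": matrix_path, "calibrations": cal_path,
            "config": config_path, "truth": truth_path,
        },
    }
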