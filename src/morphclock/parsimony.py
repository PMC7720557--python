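"""Validation-grade maximum parsimony: Fitch lengths, random-addition +
tree-bisection-reconnection search, and the implied-weighting fit score.

Characters are unordered; missing, inapplicable and ambiguity cells enter the
Fitch pass as uncertainty sets.  Unrooted topologies are represented as
adjacency maps; the Fitch count is invariant to root placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import MISSING, CharacterMatrix


class UnrootedTree:
    """Unrooted (multifurcating during construction) tree as an adjacency map."""

    def __init__(self):
        self.adj: dict[int, set[int]] = {}
        self.taxon: dict[int, str] = {}
        self._next = 0

    def new_node(self, taxon: Optional[str] = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        if taxon is not None:
            self.taxon[nid] = taxon
        return nid

    def connect(self, a: int, b: int) -> None:
        self.adj[a].add(b)
        self.adj[b].add(a)

    def disconnect(self, a: int, b: int) -> None:
        self.adj[a].discard(b)
        self.adj[b].discard(a)

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree()
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t.taxon = dict(self.taxon)
        t._next = self._next
        return t

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for a, nbrs in self.adj.items():
            for b in nbrs:
                if a < b:
                    out.append((a, b))
        return out

    def leaves(self) -> list[int]:
        return sorted(self.taxon)

    def splits(self) -> frozenset:
        """Canonical set of non-trivial bipartitions (as frozensets of taxa
        on the smaller-lexicographic side)."""
        all_taxa = frozenset(self.taxon.values())
        out = set()
        for a, b in self.edges():
            side = self._component_taxa(a, b)
            other = all_taxa - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(min(side, other, key=lambda s: sorted(s)))
        return frozenset(out)

    def _component_taxa(self, start: int, blocked: int) -> frozenset:
        seen = {start}
        stack = [start]
        taxa = set()
        while stack:
            n = stack.pop()
            if n in self.taxon:
                taxa.add(self.taxon[n])
            for m in self.adj[n]:
                if m != blocked and m not in seen:
                    seen.add(m)
                    stack.append(m)
        return frozenset(taxa)

    def subdivide(self, a: int, b: int) -> int:
        """Insert a new node on edge (a, b) and return it."""
        self.disconnect(a, b)
        mid = self.new_node()
        self.connect(a, mid)
        self.connect(mid, b)
        return mid

    def splice(self, node: int) -> None:
        """Remove a degree-2 node, joining its two neighbors."""
        nbrs = list(self.adj[node])
        assert len(nbrs) == 2
        self.disconnect(node, nbrs[0])
        self.disconnect(node, nbrs[1])
        self.connect(nbrs[0], nbrs[1])
        del self.adj[node]


def _tip_masks(matrix: CharacterMatrix) -> dict[str, np.ndarray]:
    """Per-taxon bitmask arrays (one int per character)."""
    out = {}
    for i, taxon in enumerate(matrix.taxon_names):
        masks = np.zeros(matrix.n_characters, dtype=np.int64)
        for j in range(matrix.n_characters):
            c = matrix.cells[i][j]
            k = matrix.char_state_counts[j]
            if c is MISSING:
                masks[j] = (1 << k) - 1
            elif isinstance(c, frozenset):
                m = 0
                for s in c:
                    m |= 1 << s
                masks[j] = m
            else:
                masks[j] = 1 << c
        out[taxon] = masks
    return out


def fitch_steps_per_character(tree: UnrootedTree,
                              tip_masks: dict[str, np.ndarray]) -> np.ndarray:
    """Fitch set-intersection step counts per character (polytomy-aware via
    pairwise folding)."""
    leaves = tree.leaves()
    root = leaves[0]
    n_char = len(next(iter(tip_masks.values())))
    steps = np.zeros(n_char, dtype=np.int64)

    order: list[tuple[int, int]] = []  # (node, parent) in dfs preorder
    seen = {root}
    stack = [(root, -1)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for m in tree.adj[node]:
            if m not in seen:
                seen.add(m)
                stack.append((m, node))

    masks: dict[int, np.ndarray] = {}
    for node, parent in reversed(order):
        children = [m for m in tree.adj[node] if m != parent]
        if not children:
            masks[node] = tip_masks[tree.taxon[node]]
            continue
        cur = tip_masks[tree.taxon[node]] if node in tree.taxon else None
        for ch in children:
            other = masks[ch]
            if cur is None:
                cur = other
                continue
            inter = cur & other
            empty = inter == 0
            steps += empty
            cur = np.where(empty, cur | other, inter)
        masks[node] = cur
    return steps


def fitch_length(tree: UnrootedTree, matrix: CharacterMatrix) -> int:
    taxa = set(tree.taxon.values())
    if taxa != set(matrix.taxon_names):
        raise ValueError("tree and matrix taxa differ")
    return int(fitch_steps_per_character(tree, _tip_masks(matrix)).sum())


def min_steps_per_character(matrix: CharacterMatrix) -> np.ndarray:
    """Minimum conceivable steps: observed unambiguous states minus one."""
    out = np.zeros(matrix.n_characters, dtype=np.int64)
    for j in range(matrix.n_characters):
        observed = set()
        for i in range(matrix.n_taxa):
            c = matrix.cells[i][j]
            if isinstance(c, int):
                observed.add(c)
        out[j] = max(len(observed) - 1, 0)
    return out


def implied_weight_fit(steps: np.ndarray, min_steps: np.ndarray, K: float) -> float:
    """Goloboff fit sum K/(K + h_i) with homoplasy h_i = steps - min steps."""
    h = np.maximum(steps - min_steps, 0)
    return float(np.sum(K / (K + h)))


@dataclass
class ParsimonyResult:
    best_length: int
    best_fit: Optional[float]
    trees: list[UnrootedTree]
    steps_per_character: np.ndarray
    homoplasy: np.ndarray


def _score(tree, tip_masks, mins, weighting, K):
    steps = fitch_steps_per_character(tree, tip_masks)
    if weighting == "equal":
        return float(steps.sum()), steps
    return -implied_weight_fit(steps, mins, K), steps


def _random_addition(matrix: CharacterMatrix, tip_masks, mins, weighting, K, rng):
    taxa = list(matrix.taxon_names)
    rng.shuffle(taxa)
    tree = UnrootedTree()
    hub = tree.new_node()
    for t in taxa[:3]:
        tree.connect(hub, tree.new_node(t))
    for t in taxa[3:]:
        best = None
        for a, b in tree.edges():
            cand = tree.copy()
            mid = cand.subdivide(a, b)
            cand.connect(mid, cand.new_node(t))
            sc, _ = _score(cand, tip_masks, mins, weighting, K)
            if best is None or sc < best[0]:
                best = (sc, cand)
        tree = best[1]
    return tree


def _tbr_neighbors(tree: UnrootedTree):
    """Yield all tree-bisection-reconnection rearrangements."""
    for a, b in tree.edges():
        base = tree.copy()
        base.disconnect(a, b)
        side_a = _component_nodes(base, a)
        rep_a = a if len(side_a) == 1 else next(iter(side_a - {a}))
        rep_b = b if len(_component_nodes(base, b)) == 1 else next(
            iter(_component_nodes(base, b) - {b}))
        for end in (a, b):
            if end not in base.taxon and len(base.adj[end]) == 2:
                base.splice(end)
        nodes_a = _component_nodes(base, rep_a)
        nodes_b = set(base.adj) - nodes_a
        if not nodes_b:
            continue
        edges_a = [e for e in base.edges() if e[0] in nodes_a]
        edges_b = [e for e in base.edges() if e[0] in nodes_b]
        att_a = edges_a or [(_single(nodes_a), None)]
        att_b = edges_b or [(_single(nodes_b), None)]
        for ea in att_a:
            for eb in att_b:
                cand = base.copy()
                pa = cand.subdivide(*ea) if ea[1] is not None else ea[0]
                pb = cand.subdivide(*eb) if eb[1] is not None else eb[0]
                cand.connect(pa, pb)
                yield cand


def _single(nodes):
    assert len(nodes) == 1
    return next(iter(nodes))


def _component_nodes(tree: UnrootedTree, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        n = stack.pop()
        for m in tree.adj[n]:
            if m not in seen:
                seen.add(m)
                stack.append(m)
    return seen


def heuristic_search(matrix: CharacterMatrix, n_ras: int = 10, hold: int = 5,
                     weighting: str = "equal", K: float = 12.0,
                     seed: int = 1) -> ParsimonyResult:
    """Random-addition-sequence starts followed by TBR hill climbing.

    ``weighting='equal'`` minimizes total steps; ``'implied'`` maximizes the
    concave fit sum with concavity constant ``K``.  Seeded and reproducible.
    """
    if weighting not in ("equal", "implied"):
        raise ValueError("weighting must be 'equal' or 'implied'")
    rng = np.random.default_rng(seed)
    tip_masks = _tip_masks(matrix)
    mins = min_steps_per_character(matrix)

    best_trees: list[tuple[float, UnrootedTree]] = []
    seen_splits = set()
    for _ in range(max(n_ras, 1)):
        tree = _random_addition(matrix, tip_masks, mins, weighting, K, rng)
        score, _ = _score(tree, tip_masks, mins, weighting, K)
        improved = True
        while improved:
            improved = False
            for cand in _tbr_neighbors(tree):
                sc, _ = _score(cand, tip_masks, mins, weighting, K)
                if sc < score - 1e-12:
                    tree, score = cand, sc
                    improved = True
                    break
        key = tree.splits()
        if key not in seen_splits:
            seen_splits.add(key)
            best_trees.append((score, tree))
    best_trees.sort(key=lambda x: x[0])
    best_trees = best_trees[:hold]
    best_score, best_tree = best_trees[0]
    steps = fitch_steps_per_character(best_tree, tip_masks)
    return ParsimonyResult(
        best_length=int(steps.sum()),
        best_fit=(implied_weight_fit(steps, mins, K) if weighting == "implied" else None),
        trees=[t for _, t in best_trees],
        steps_per_character=steps,
        homoplasy=np.maximum(steps - mins, 0),
    )


def all_unrooted_topologies(taxa: list[str]):
    """Enumerate all unrooted binary topologies (tiny n; exhaustive oracle)."""
    if len(taxa) < 3:
        raise ValueError("need at least three taxa")
    base = UnrootedTree()
    hub = base.new_node()
    for t in taxa[:3]:
        base.connect(hub, base.new_node(t))
    trees = [base]
    for t in taxa[3:]:
        nxt = []
        for tr in trees:
            for a, b in tr.edges():
                cand = tr.copy()
                mid = cand.subdivide(a, b)
                cand.connect(mid, cand.new_node(t))
                nxt.append(cand)
        trees = nxt
    return trees
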