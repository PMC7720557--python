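"""Rooted time trees with node ages, sampled-ancestor flags and branch annotations.

Conventions
-----------
Ages are in Ma before present and increase rootward; an edge's *duration* is
``parent.age - child.age`` (Myr).  Expected-substitution branch lengths are a
separate quantity produced by the clock models and are stored per node in
``node.meta`` when needed.

A *sampled ancestor* is represented MrBayes-style as a fossil tip attached by a
zero-duration branch: its parent node has the same age as the tip and is a
degree-2 point on the host lineage rather than a speciation event.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional

import dendropy

_AGE_TOL = 1e-9


class Node:
    __slots__ = ("parent", "children", "age", "taxon", "meta")

    def __init__(self, age: float = 0.0, taxon: Optional[str] = None):
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.age = float(age)
        self.taxon = taxon
        self.meta: dict = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.taxon or 'internal'} age={self.age:.3f}>"


class TimeTree:
    """A rooted, age-calibrated tree."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ walks
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internals(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def taxa(self) -> list[str]:
        return sorted(n.taxon for n in self.leaves())

    def find_leaf(self, taxon: str) -> Node:
        for n in self.leaves():
            if n.taxon == taxon:
                return n
        raise KeyError(taxon)

    # -------------------------------------------------------------- structure
    def duration(self, node: Node) -> float:
        if node.parent is None:
            return 0.0
        return node.parent.age - node.age

    def is_sampled_ancestor(self, node: Node) -> bool:
        """True for a fossil tip attached by a zero-duration branch."""
        return (
            node.is_leaf
            and node.parent is not None
            and abs(node.parent.age - node.age) <= _AGE_TOL
            and node.age > _AGE_TOL
        )

    def sampled_ancestors(self) -> list[Node]:
        return [n for n in self.leaves() if self.is_sampled_ancestor(n)]

    def sa_attachment(self, node: Node) -> bool:
        """True if ``node`` is the degree-2 point hosting a sampled ancestor."""
        if node.is_leaf or node.parent is None and False:
            return False
        return any(
            c.is_leaf and abs(c.age - node.age) <= _AGE_TOL and c.age > _AGE_TOL
            for c in node.children
        )

    def n_extant(self) -> int:
        return sum(1 for n in self.leaves() if n.age <= _AGE_TOL)

    def validate(self) -> None:
        for node in self.preorder():
            for c in node.children:
                if c.age - node.age > _AGE_TOL:
                    raise ValueError(
                        f"child older than parent: {c.age} > {node.age}"
                    )
        names = [n.taxon for n in self.leaves()]
        if len(names) != len(set(names)):
            raise ValueError("duplicate taxon labels on tree")

    # ------------------------------------------------------------------ edits
    def copy(self) -> "TimeTree":
        def _clone(node: Node) -> Node:
            new = Node(node.age, node.taxon)
            new.meta = dict(node.meta)
            for c in node.children:
                new.add_child(_clone(c))
            return new

        return TimeTree(_clone(self.root))

    def remove_knuckles(self) -> None:
        """Collapse degree-2 internal nodes that are not SA attachments."""
        changed = True
        while changed:
            changed = False
            for node in list(self.preorder()):
                if not node.is_leaf and len(node.children) == 1:
                    child = node.children[0]
                    if node.parent is None:
                        child.parent = None
                        self.root = child
                    else:
                        parent = node.parent
                        parent.children[parent.children.index(node)] = child
                        child.parent = parent
                    changed = True
                    break

    # ------------------------------------------------------------- bitstrings
    def clades(self, taxon_index: Optional[dict[str, int]] = None) -> dict[Node, frozenset]:
        """Map each node to the frozenset of leaf taxa below it."""
        out: dict[Node, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node] = frozenset([node.taxon])
            else:
                out[node] = frozenset(itertools.chain(*(out[c] for c in node.children)))
        return out

    # ---------------------------------------------------------------- newick
    def to_newick(self, annotate: bool = False, digits: int = 6) -> str:
        def _meta(node: Node) -> str:
            if not annotate or not node.meta:
                return ""
            body = ",".join(f"{k}={_fmt(v)}" for k, v in sorted(node.meta.items()))
            return f"[&{body}]"

        def _fmt(v):
            if isinstance(v, float):
                return f"{v:.{digits}g}"
            if isinstance(v, (tuple, list)):
                return "{" + ",".join(_fmt(x) for x in v) + "}"
            return str(v)

        def _rec(node: Node) -> str:
            if node.is_leaf:
                core = node.taxon
            else:
                core = "(" + ",".join(_rec(c) for c in node.children) + ")"
            blen = self.duration(node)
            if node.parent is None:
                return core + _meta(node)
            return f"{core}{_meta(node)}:{blen:.{digits}f}"

        return _rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, tip_ages: Optional[dict[str, float]] = None) -> "TimeTree":
        """Parse newick (optionally with ``[&key=value]`` comments) to a TimeTree.

        Branch lengths are read as durations (Myr).  Node ages are
        reconstructed from root-to-tip path lengths; if ``tip_ages`` is given
        it is used to anchor the age of the youngest tip, otherwise the
        youngest tip is placed at age 0.
        """
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", extract_comment_metadata=True,
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
        root = Node(0.0)
        depth: dict[Node, float] = {root: 0.0}
        _copy_annotations(dtree.seed_node, root)

        def _walk(dnode, node):
            for dchild in dnode.child_nodes():
                child = Node(0.0, taxon=dchild.taxon.label if dchild.taxon else None)
                node.add_child(child)
                depth[child] = depth[node] + (dchild.edge.length or 0.0)
                _copy_annotations(dchild, child)
                _walk(dchild, child)

        _walk(dtree.seed_node, root)
        tree = cls(root)
        max_depth = max(depth[n] for n in tree.leaves())
        offset = 0.0
        if tip_ages:
            leaf = tree.leaves()[0]
            offset = tip_ages[leaf.taxon] - (max_depth - depth[leaf])
        for node in tree.preorder():
            node.age = max_depth - depth[node] + offset
        return tree


def _copy_annotations(dnode, node: Node) -> None:
    for ann in dnode.annotations:
        val = ann.value
        try:
            val = float(val)
        except (TypeError, ValueError):
            pass
        node.meta[ann.name] = val


def balanced_tree(taxa: list[str], root_age: float) -> TimeTree:
    """Deterministic caterpillar tree with evenly spaced node ages (utility)."""
    nodes = [Node(0.0, t) for t in taxa]
    ages = [root_age * (i + 1) / (len(taxa) - 1) for i in range(len(taxa) - 1)]
    current = nodes[0]
    for i, tip in enumerate(nodes[1:]):
        parent = Node(ages[i])
        parent.add_child(current)
        parent.add_child(tip)
        current = parent
    return TimeTree(current)


def random_calibrated_tree(taxa_ages: dict[str, float], root_age: float, rng) -> TimeTree:
    """Random topology with node ages compatible with the given tip ages.

    Coalescent-style construction: repeatedly join the two oldest-compatible
    lineages at an age drawn above both, below ``root_age``.
    """
    lineages = [Node(a, t) for t, a in taxa_ages.items()]
    max_tip = max(taxa_ages.values())
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a, b = lineages[i], lineages[j]
        low = max(a.age, b.age, max_tip if len(lineages) == 2 else 0.0)
        if len(lineages) == 2:
            age = root_age
        else:
            age = low + (root_age - low) * rng.beta(1.5, 3.0)
        parent = Node(age)
        parent.add_child(a)
        parent.add_child(b)
        lineages = [n for k, n in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    tree = TimeTree(lineages[0])
    tree.validate()
    return tree
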