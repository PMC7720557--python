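"""Posterior tree summarization: majority-rule consensus (MRC), maximum
compatibility trees (MCT), highest-posterior-density intervals, and
per-branch relative evolutionary rates.

Node ages are summarized as medians (posterior age distributions are broad
and skewed); after independent per-clade summarization a child median may
exceed its parent's, in which case the child is clipped to the parent age
and the number of repairs reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mcmc import PosteriorSample
from .treedata import Node, TimeTree


@dataclass
class CladeSummary:
    clade: frozenset
    posterior: float
    median_age: float
    hpd_low: float
    hpd_high: float
    median_rel_rate: dict[str, float] = field(default_factory=dict)

    @property
    def hpd_range(self) -> float:
        return self.hpd_high - self.hpd_low

    def rate_label(self, partition: str = "all") -> str:
        r = self.median_rel_rate.get(partition, 1.0)
        return "accelerating" if r > 1.0 else ("decelerating" if r < 1.0 else "clock-like")


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ``ceil(mass * n)`` sorted values."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    if n < 20:
        import warnings
        warnings.warn("fewer than 20 samples; HPD estimate is unstable")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 + np.arange(n - m + 1)] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


# --------------------------------------------------------------------------
# Clade bookkeeping
# --------------------------------------------------------------------------

def _collect(samples: list[PosteriorSample]):
    """Per-clade ages, relative rates and counts over all samples."""
    if not samples:
        raise ValueError("empty posterior sample")
    n = len(samples)
    ages: dict[frozenset, list[float]] = {}
    rates: dict[frozenset, dict[str, list[float]]] = {}
    counts: dict[frozenset, int] = {}
    for s in samples:
        clades = s.tree.clades()
        for node, clade in clades.items():
            counts[clade] = counts.get(clade, 0) + 1
            ages.setdefault(clade, []).append(node.age)
            rr = rates.setdefault(clade, {})
            for key, val in node.meta.items():
                if key.startswith("rel_rate_"):
                    rr.setdefault(key[len("rel_rate_"):], []).append(val)
    return counts, ages, rates, n


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a.isdisjoint(b) or a <= b or b <= a


def _build_tree(clades: list[frozenset], summaries: dict[frozenset, CladeSummary],
                taxa: frozenset) -> TimeTree:
    """Assemble a tree from a nested, compatible clade set."""
    ordered = sorted(set(clades) | {taxa}, key=lambda c: (len(c), sorted(c)))
    nodes: dict[frozenset, Node] = {}
    repairs = 0
    for clade in ordered:
        summ = summaries.get(clade)
        node = Node(summ.median_age if summ else 0.0,
                    taxon=(next(iter(clade)) if len(clade) == 1 else None))
        if summ:
            node.meta.update({
                "posterior": summ.posterior,
                "age_median": summ.median_age,
                "age_hpd_low": summ.hpd_low,
                "age_hpd_high": summ.hpd_high,
            })
            for lab, r in summ.median_rel_rate.items():
                node.meta[f"rel_rate_{lab}"] = r
        nodes[clade] = node
    for clade in ordered:
        if clade == taxa:
            continue
        parents = [c for c in ordered if clade < c]
        parent = min(parents, key=len)
        nodes[parent].add_child(nodes[clade])
    tree = TimeTree(nodes[taxa])
    # clip child medians that exceed the parent median
    for node in tree.preorder():
        if node.parent is not None and node.age > node.parent.age:
            node.age = node.parent.age
            repairs += 1
    tree.root.meta["n_age_repairs"] = repairs
    return tree


def _summarize_clades(samples, clade_list, counts, ages, rates, n):
    out = {}
    for clade in clade_list:
        a = np.asarray(ages[clade])
        lo, hi = hpd_interval(a) if len(a) >= 2 else (float(a[0]), float(a[0]))
        out[clade] = CladeSummary(
            clade=clade,
            posterior=counts[clade] / n,
            median_age=float(np.median(a)),
            hpd_low=lo,
            hpd_high=hi,
            median_rel_rate={lab: float(np.median(v))
                             for lab, v in rates[clade].items() if v},
        )
    return out


def majority_rule_consensus(samples: list[PosteriorSample],
                            threshold: float = 0.5) -> tuple[TimeTree, dict]:
    """50% (or ``threshold``) majority-rule consensus with median ages,
    95% HPD bounds, posterior probabilities and median relative rates."""
    counts, ages, rates, n = _collect(samples)
    taxa = max(counts, key=len)
    keep = [c for c, k in counts.items() if k / n > threshold and c != taxa]
    summaries = _summarize_clades(samples, set(keep) | {taxa}, counts, ages, rates, n)
    tree = _build_tree(keep, summaries, taxa)
    return tree, summaries


def maximum_compatibility_tree(samples: list[PosteriorSample]) -> tuple[TimeTree, dict]:
    """Greedy clade insertion in decreasing posterior frequency; ties broken
    by the lexicographic order of the sorted taxon sets."""
    counts, ages, rates, n = _collect(samples)
    taxa = max(counts, key=len)
    ordered = sorted((c for c in counts if c != taxa),
                     key=lambda c: (-counts[c], sorted(c)))
    accepted: list[frozenset] = []
    for clade in ordered:
        if all(_compatible(clade, other) for other in accepted):
            accepted.append(clade)
    summaries = _summarize_clades(samples, set(accepted) | {taxa}, counts, ages, rates, n)
    tree = _build_tree(accepted, summaries, taxa)
    return tree, summaries


def relative_branch_rates(samples: list[PosteriorSample]) -> dict[frozenset, dict[str, float]]:
    """Per-clade median relative rate (branch rate / base rate) per
    partition; requires clock samples carrying rate annotations."""
    counts, ages, rates, n = _collect(samples)
    out = {}
    for clade, rr in rates.items():
        if rr:
            out[clade] = {lab: float(np.median(v)) for lab, v in rr.items()}
    if not out:
        raise ValueError("samples carry no branch-rate annotations (non-clock run?)")
    return out


def divergence_table(summaries_per_model: dict[str, dict[frozenset, CladeSummary]],
                     focal_clades: dict[str, frozenset]) -> pd.DataFrame:
    """Tables 1-3 style layout: per focal clade and model label, the median
    age M and the 95% HPD range."""
    rows = []
    for model, summaries in summaries_per_model.items():
        for name, clade in focal_clades.items():
            s = summaries.get(clade)
            rows.append({
                "model": model,
                "clade": name,
                "M": s.median_age if s else np.nan,
                "HPD_low": s.hpd_low if s else np.nan,
                "HPD_high": s.hpd_high if s else np.nan,
                "Rng_HPD": s.hpd_range if s else np.nan,
                "posterior": s.posterior if s else 0.0,
            })
    return pd.DataFrame(rows)
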