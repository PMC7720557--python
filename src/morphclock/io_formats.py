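"""Readers and writers for every external format the pipeline touches.

* NEXUS morphological matrices (digit symbols, ``?`` missing, ``-``
  inapplicable, ``{..}``/``(..)`` ambiguity sets),
* calibration tables (CSV: taxon, age_min, age_max in Ma),
* Newick/NEXUS trees with bracketed ``[&key=value]`` metadata comments,
* structured run configurations (YAML/JSON).

Inapplicable scores are folded into missing for likelihood purposes, and
ambiguity sets contribute partial likelihood 1 for each included state --
the standard Mk uncertainty conventions.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
import yaml

from .treedata import TimeTree

MISSING = None
Cell = Union[int, None, frozenset]


class ParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


class AscertainmentWarning(UserWarning):
    """A character violates the variable-characters-only assumption."""


# --------------------------------------------------------------------------
# Character matrix
# --------------------------------------------------------------------------

@dataclass
class CharacterMatrix:
    """Taxa x characters of coded states.

    ``cells[i][j]`` is a dense state index in ``0..k_j-1``, ``None`` for
    missing/inapplicable, or a frozenset of state indices for ambiguity.
    ``char_state_counts[j]`` is the number of observed states ``k_j``.
    """

    taxon_names: list[str]
    cells: list[list[Cell]]
    char_state_counts: list[int]
    partition_map: Optional[list[str]] = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_characters(self) -> int:
        return len(self.char_state_counts)

    def column(self, j: int) -> list[Cell]:
        return [row[j] for row in self.cells]

    def cell_state_set(self, i: int, j: int) -> Optional[frozenset]:
        """States consistent with cell (i, j); None when missing."""
        c = self.cells[i][j]
        if c is MISSING:
            return None
        if isinstance(c, frozenset):
            return c
        return frozenset([c])

    def is_variable(self, j: int) -> bool:
        """A character is constant iff one state is consistent with every
        scored cell; variable otherwise."""
        sets = [s for i in range(self.n_taxa) if (s := self.cell_state_set(i, j))]
        if not sets:
            return False
        common = frozenset.intersection(*sets)
        return len(common) == 0

    def subset(self, char_idx: Sequence[int]) -> "CharacterMatrix":
        return CharacterMatrix(
            taxon_names=list(self.taxon_names),
            cells=[[row[j] for j in char_idx] for row in self.cells],
            char_state_counts=[self.char_state_counts[j] for j in char_idx],
            partition_map=(
                [self.partition_map[j] for j in char_idx] if self.partition_map else None
            ),
        )

    def partition_subsets(self, default: str = "unassigned") -> dict[str, "CharacterMatrix"]:
        """Split by partition label; unlabeled characters go to ``default``."""
        labels = self.partition_map or [default] * self.n_characters
        labels = [lab if lab is not None else default for lab in labels]
        out = {}
        for lab in dict.fromkeys(labels):
            idx = [j for j, l in enumerate(labels) if l == lab]
            out[lab] = self.subset(idx)
        return out

    def is_direct_autapomorphy(self, j: int) -> bool:
        """True when the character is variable only through a single taxon:
        all scored taxa except one are consistent with a shared state."""
        sets = [s for i in range(self.n_taxa) if (s := self.cell_state_set(i, j))]
        if len(sets) < 3 or not self.is_variable(j):
            return False
        for drop in range(len(sets)):
            rest = sets[:drop] + sets[drop + 1:]
            if frozenset.intersection(*rest):
                return True
        return False

    def autapomorphy_fraction(self) -> float:
        n = self.n_characters
        return sum(self.is_direct_autapomorphy(j) for j in range(n)) / n

    def validate(self, constant_characters: str = "warn") -> None:
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise ValidationError("duplicate taxon labels")
        for row in self.cells:
            if len(row) != self.n_characters:
                raise ValidationError("ragged matrix rows")
        for j in range(self.n_characters):
            if not self.is_variable(j):
                msg = f"character {j} is constant (variable-only ascertainment)"
                if constant_characters == "error":
                    raise ValidationError(msg)
                warnings.warn(msg, AscertainmentWarning)


def _parse_cell(token: str, line_no: int) -> Union[frozenset, int, None, str]:
    if token in ("?", "-"):
        return MISSING
    if token.isdigit() and len(token) == 1:
        return int(token)
    if token.startswith(("{", "(")) and token.endswith(("}", ")")):
        inner = [c for c in token[1:-1] if c.isdigit()]
        if not inner:
            raise ParseError(f"line {line_no}: empty ambiguity set {token!r}")
        return frozenset(int(c) for c in inner)
    raise ParseError(f"line {line_no}: unrecognized cell symbol {token!r}")


def read_nexus_matrix(
    path: str,
    partition_map: Optional[dict[int, str]] = None,
    constant_characters: str = "warn",
) -> CharacterMatrix:
    """Read a NEXUS CHARACTERS/DATA block of digit-coded states.

    States are recoded densely per character (observed states -> 0..k-1);
    ``-`` maps to missing and ``{..}``/``(..)`` to ambiguity sets.
    """
    with open(path) as fh:
        text = fh.read()
    taxa, rows = _tokenize_nexus_matrix(text)
    if len(set(taxa)) != len(taxa):
        raise ValidationError("duplicate taxon label in NEXUS matrix")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ParseError(f"unequal row lengths: {sorted(lengths)}")

    n_char = lengths.pop()
    cells: list[list[Cell]] = [[None] * n_char for _ in taxa]
    counts: list[int] = []
    for j in range(n_char):
        observed: set[int] = set()
        for i in range(len(taxa)):
            c = rows[i][j]
            if c is MISSING:
                continue
            observed |= c if isinstance(c, frozenset) else {c}
        recode = {s: d for d, s in enumerate(sorted(observed))}
        counts.append(max(len(observed), 2))
        for i in range(len(taxa)):
            c = rows[i][j]
            if c is MISSING:
                cells[i][j] = MISSING
            elif isinstance(c, frozenset):
                cells[i][j] = frozenset(recode[s] for s in c)
            else:
                cells[i][j] = recode[c]

    if partition_map is None:
        partition_map = _parse_charsets(text)
    pmap = None
    if partition_map:
        pmap = [partition_map.get(j) for j in range(n_char)]
    matrix = CharacterMatrix(list(taxa), cells, counts, pmap)
    matrix.validate(constant_characters=constant_characters)
    return matrix


def _tokenize_nexus_matrix(text: str):
    lines = text.splitlines()
    in_matrix = False
    taxa: list[str] = []
    rows: list[list] = []
    saw_block = False
    for line_no, raw in enumerate(lines, start=1):
        line = raw.split("[")[0].strip()  # strip NEXUS comments (single-line)
        lower = line.lower()
        if lower.startswith("begin") and ("characters" in lower or "data" in lower):
            saw_block = True
        if lower == "matrix":
            in_matrix = True
            continue
        if not in_matrix:
            continue
        if lower.startswith(("end;", ";")):
            break
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"line {line_no}: expected 'taxon states', got {raw!r}")
        name, seq = parts
        seq = seq.rstrip(";").strip()
        row: list = []
        k = 0
        while k < len(seq):
            ch = seq[k]
            if ch.isspace():
                k += 1
                continue
            if ch in "{(":
                close = "}" if ch == "{" else ")"
                end = seq.find(close, k)
                if end < 0:
                    raise ParseError(f"line {line_no}: unclosed ambiguity set")
                row.append(_parse_cell(seq[k:end + 1], line_no))
                k = end + 1
            else:
                row.append(_parse_cell(ch, line_no))
                k += 1
        taxa.append(name.strip("'\""))
        rows.append(row)
    if not saw_block or not taxa:
        raise ParseError("no CHARACTERS/DATA matrix block found")
    return taxa, rows


def _parse_charsets(text: str) -> dict[int, str]:
    """CHARSET lines (1-based, ``a-b`` ranges) -> 0-based partition map."""
    import re

    out: dict[int, str] = {}
    for name, body in re.findall(r"(?im)^\s*charset\s+(\S+)\s*=\s*([^;]+);", text):
        for token in body.split():
            if "-" in token:
                a, b = token.split("-")
                for j in range(int(a) - 1, int(b)):
                    out[j] = name
            else:
                out[int(token) - 1] = name
    return out


def write_nexus_matrix(matrix: CharacterMatrix, path: str) -> None:
    width = max(len(t) for t in matrix.taxon_names) + 2
    max_state = max(matrix.char_state_counts)
    symbols = " ".join(str(i) for i in range(max_state))
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n")
        fh.write(f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n')
        fh.write("  MATRIX\n")
        for i, name in enumerate(matrix.taxon_names):
            chunks = []
            for c in matrix.cells[i]:
                if c is MISSING:
                    chunks.append("?")
                elif isinstance(c, frozenset):
                    chunks.append("{" + "".join(str(s) for s in sorted(c)) + "}")
                else:
                    chunks.append(str(c))
            fh.write(f"  {name:<{width}}{''.join(chunks)}\n")
        fh.write("  ;\nEND;\n")
        if matrix.partition_map and any(matrix.partition_map):
            fh.write("\nBEGIN SETS;\n")
            for label in dict.fromkeys(matrix.partition_map):
                if label is None:
                    continue
                idx = [j + 1 for j, l in enumerate(matrix.partition_map)
                       if l == label]
                fh.write(f"  CHARSET {label} = {_ranges(idx)};\n")
            fh.write("END;\n")


def _ranges(indices: list[int]) -> str:
    parts = []
    start = prev = indices[0]
    for i in indices[1:] + [None]:
        if i is not None and i == prev + 1:
            prev = i
            continue
        parts.append(f"{start}-{prev}" if prev > start else str(start))
        if i is not None:
            start = prev = i
    return " ".join(parts)


# --------------------------------------------------------------------------
# Calibrations
# --------------------------------------------------------------------------

@dataclass
class Calibration:
    age_min: float
    age_max: float

    @property
    def is_extant(self) -> bool:
        return self.age_min == 0.0 and self.age_max == 0.0


@dataclass
class CalibrationTable:
    entries: dict[str, Calibration]

    def __getitem__(self, taxon: str) -> Calibration:
        return self.entries[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.entries

    def taxa(self) -> list[str]:
        return list(self.entries)

    def extant_taxa(self) -> list[str]:
        return [t for t, c in self.entries.items() if c.is_extant]

    def fossil_taxa(self) -> list[str]:
        return [t for t, c in self.entries.items() if not c.is_extant]

    def validate(self, matrix: Optional[CharacterMatrix] = None) -> None:
        for taxon, cal in self.entries.items():
            if cal.age_min < 0 or cal.age_min > cal.age_max:
                raise ValidationError(
                    f"{taxon}: invalid age range [{cal.age_min}, {cal.age_max}]"
                )
        if matrix is not None:
            unknown = set(self.entries) - set(matrix.taxon_names)
            if unknown:
                raise ValidationError(f"calibrated taxa absent from matrix: {sorted(unknown)}")


def read_calibrations(path: str, matrix: Optional[CharacterMatrix] = None) -> CalibrationTable:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        tcol, mincol, maxcol = cols["taxon"], cols["age_min"], cols["age_max"]
    except KeyError as exc:
        raise ParseError(f"calibration table missing column {exc}") from exc
    entries = {}
    for _, row in df.iterrows():
        entries[str(row[tcol])] = Calibration(float(row[mincol]), float(row[maxcol]))
    table = CalibrationTable(entries)
    table.validate(matrix)
    return table


def write_calibrations(table: CalibrationTable, path: str) -> None:
    rows = [
        {"taxon": t, "age_min": c.age_min, "age_max": c.age_max, "is_extant": c.is_extant}
        for t, c in table.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

_ENUMS = {
    "acrv_kind": {"gamma", "lognormal", "none"},
    "freq_model": {"symmetric", "asymmetric"},
    "clock_model": {"strict", "igr", "tk02", "none"},
    "sampling_strategy": {"fossiltip", "random", "diversity", "nosa_diversity"},
    "root_prior_kind": {"offset_exponential", "truncated_normal"},
    "base_rate_prior_kind": {"lognormal", "gamma"},
    "skyline_mask": {"s", "sdr"},
}


@dataclass
class RunConfig:
    """Structured description of one analysis (model x priors x MCMC settings)."""

    # substitution model
    acrv_kind: str = "gamma"
    n_rate_categories: int = 4
    freq_model: str = "symmetric"
    alpha_dir_bounds: tuple[float, float] = (0.05, 20.0)
    n_freq_categories: int = 4
    # clock
    clock_model: str = "igr"
    base_rate_prior_kind: str = "lognormal"
    base_rate_prior_params: tuple[float, ...] = (0.02, 1.0202)  # (mean, sd-scale)
    clock_var_prior_rate: float = 10.0
    # tree model
    sampling_strategy: str = "fossiltip"
    rho: float = 1.0
    x_cut: float = 0.0
    shift_times: tuple[float, ...] = ()
    skyline_mask: str = "s"
    diversification_prior_rate: float = 10.0
    low_extinction_prior: bool = False  # Beta(1,9) on turnover instead of uniform
    # root calibration
    root_prior_kind: str = "offset_exponential"
    root_prior_params: tuple[float, ...] = (247.2, 287.0)  # offset, mean
    # partitioning
    partitions: Optional[dict[str, list[int]]] = None
    unlink_clocks: bool = True
    # constraints
    fix_topology: bool = False
    fix_clock_rate: bool = False
    starting_tree: Optional[str] = None  # newick
    # MCMC
    n_generations: int = 10000
    n_runs: int = 2
    sample_interval: int = 20
    burn_in: float = 0.25
    seed: int = 1
    move_weights: dict = field(default_factory=dict)
    label: str = "run"

    def __post_init__(self):
        for key, allowed in _ENUMS.items():
            if getattr(self, key) not in allowed:
                raise ValidationError(f"{key}={getattr(self, key)!r} not in {sorted(allowed)}")
        if not (0 <= self.burn_in < 1):
            raise ValidationError("burn_in must be in [0, 1)")
        if self.sampling_strategy in ("diversity", "nosa_diversity") and self.x_cut <= 0:
            raise ValidationError("diversity sampling requires x_cut > 0")

    @property
    def sampled_ancestors_allowed(self) -> bool:
        return self.sampling_strategy in ("random", "diversity")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("alpha_dir_bounds", "base_rate_prior_params", "shift_times",
                    "root_prior_params"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# Annotated trees
# --------------------------------------------------------------------------

def write_annotated_tree(tree: TimeTree, path: str, annotations: Optional[dict] = None,
                         translate: bool = True) -> None:
    """Write a NEXUS trees block with bracketed metadata comments.

    ``annotations`` maps node -> dict of extra key/values merged into each
    node's ``meta`` before writing.  Negative branch durations are refused.
    """
    tree.validate()
    work = tree.copy()
    if annotations:
        by_clade = {k: v for k, v in annotations.items()}
        clades = work.clades()
        for node in work.preorder():
            extra = by_clade.get(clades[node])
            if extra:
                node.meta.update(extra)
    for node in work.preorder():
        if work.is_sampled_ancestor(node):
            node.meta["sampled_ancestor"] = "true"
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN TREES;\n")
        fh.write(f"  TREE summary = [&R] {work.to_newick(annotate=True)}\n")
        fh.write("END;\n")


def read_annotated_tree(path: str) -> TimeTree:
    dlist = dendropy.TreeList.get(path=path, schema="nexus",
                                  extract_comment_metadata=True,
                                  preserve_underscores=True)
    newick = dlist[0].as_string(schema="newick", suppress_annotations=False,
                                suppress_rooting=True)
    tree = TimeTree.from_newick(newick)
    # restore fossil tip ages encoded in metadata where present
    return tree


def write_trace(samples: list[dict], path: str) -> None:
    pd.DataFrame(samples).to_csv(path, sep="\t", index=False)


def read_trace(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_run_log(path: str, config: RunConfig, extra: Optional[dict] = None) -> None:
    payload = {"config": _jsonable(config.to_dict())}
    if extra:
        payload.update(_jsonable(extra))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
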