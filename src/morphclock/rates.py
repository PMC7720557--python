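"""Downstream regression statistics on per-node posterior summaries.

Ordinary least squares on per-clade point estimates (medians), as used to
test evolutionary integration between anatomical partitions (rate vs rate)
and node-depth precision bias (HPD range vs median age).  Statistics only;
interpretation is left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress(x, y) -> RegressionResult:
    """OLS fit of y on x with slope, intercept, R^2, p and n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 matched observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression input")
    if np.var(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2), p_value=float(fit.pvalue), n=len(x),
    )


def node_quantity_frame(summaries: dict, model: str = "model") -> pd.DataFrame:
    """Long-format per-clade table: median age, HPD range, per-partition
    median relative rate."""
    rows = []
    for clade, s in summaries.items():
        if len(clade) < 2:
            continue
        row = {
            "model": model,
            "clade": tuple(sorted(clade)),
            "median_age": s.median_age,
            "hpd_range": s.hpd_range,
        }
        for lab, r in s.median_rel_rate.items():
            row[f"rate_{lab}"] = r
        rows.append(row)
    return pd.DataFrame(rows)


def integration_report(frame: pd.DataFrame) -> pd.DataFrame:
    """All pairwise partition-rate regressions over matched clades."""
    rate_cols = [c for c in frame.columns if c.startswith("rate_")]
    if len(rate_cols) < 2:
        raise ValueError("need at least two partitions with rates")
    rows = []
    for a, b in combinations(rate_cols, 2):
        sub = frame[[a, b]].dropna()
        fit = regress(sub[a], sub[b])
        rows.append({
            "x": a[len("rate_"):], "y": b[len("rate_"):],
            "slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n,
        })
    return pd.DataFrame(rows)


def depth_bias_report(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per model: regression of HPD range on median node age.  A positive
    slope means older nodes carry wider (less precise) intervals."""
    rows = []
    for model, frame in frames.items():
        sub = frame[["median_age", "hpd_range"]].dropna()
        fit = regress(sub["median_age"], sub["hpd_range"])
        rows.append({
            "model": model, "slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n,
        })
    return pd.DataFrame(rows)
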