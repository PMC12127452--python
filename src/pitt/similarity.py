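"""Time-series similarity measures and representativeness statistics.

How well a parcel's backscatter curve represents its crop's typical
phenology is summarised by two group statistics:

* GAS (group-average similarity): the mean of all n^2 pairwise Pearson
  correlations within a group, self-pairs included;
* TAS (true-average similarity): the mean correlation of group members
  to a designated typical sample.

Both can alternatively use the time-weighted DTW *distance* (lower =
more similar), with a logistic time penalty

    omega(g) = 1 / (1 + exp(-alpha * (g - beta))),   g = |date gap| days

added to the absolute-difference local cost, so alignments that warp far
across the season are discouraged.  Defaults alpha = 0.1 / day and
beta = 5 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TWDTWParams:
    """Logistic time-weight parameters (steepness per day, midpoint days)."""

    alpha: float = 0.1
    beta: float = 5.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


def pearson(x, y, eps: float = 1e-12) -> float:
    """Pearson correlation; 0.0 for a zero-variance input (degenerate)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must share a length of at least 2")
    xs, ys = x.std(), y.std()
    if xs < eps or ys < eps:
        return 0.0
    return float(np.clip(((x - x.mean()) * (y - y.mean())).mean() / (xs * ys), -1, 1))


def time_weight(gap_days, params: TWDTWParams) -> np.ndarray:
    """Logistic warping penalty omega(g) in [0, 1]."""
    g = np.asarray(gap_days, dtype=float)
    return 1.0 / (1.0 + np.exp(-params.alpha * (g - params.beta)))


def twdtw(
    x,
    y,
    dates_x: Sequence[float] | None = None,
    dates_y: Sequence[float] | None = None,
    params: TWDTWParams = TWDTWParams(),
) -> float:
    """Time-weighted DTW distance with the symmetric step pattern.

    Local cost d(i, j) = |x_i - y_j| + omega(|t_i - t_j|); full alignment
    from (0, 0) to (n-1, m-1), steps match / insert / delete, no window.
    Dates default to indices 0..n-1 (unit day spacing).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty series")
    tx = np.arange(x.size) if dates_x is None else np.asarray(dates_x, dtype=float)
    ty = np.arange(y.size) if dates_y is None else np.asarray(dates_y, dtype=float)
    if tx.size != x.size or ty.size != y.size:
        raise ValueError("date vectors must align with the series")
    cost = np.abs(x[:, None] - y[None, :]) + time_weight(
        np.abs(tx[:, None] - ty[None, :]), params
    )
    n, m = cost.shape
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        row_prev = D[i - 1]
        row = D[i]
        for j in range(1, m):
            row[j] = cost[i, j] + min(row_prev[j - 1], row_prev[j], row[j - 1])
    return float(D[-1, -1])


def _measure(measure: str, params: TWDTWParams):
    if measure == "pearson":
        return lambda a, b, da, db: pearson(a, b)
    if measure == "twdtw":
        return lambda a, b, da, db: twdtw(a, b, da, db, params)
    raise ValueError(f"unknown measure {measure!r}")


def gas(
    group: np.ndarray,
    measure: str = "pearson",
    dates=None,
    params: TWDTWParams = TWDTWParams(),
) -> float:
    """Group-average similarity over all n^2 ordered pairs (self included)."""
    g = np.atleast_2d(np.asarray(group, dtype=float))
    n = g.shape[0]
    if n == 0:
        raise ValueError("empty group")
    if measure == "pearson":
        sd = g.std(axis=1)
        z = np.where(sd[:, None] < 1e-12, 0.0, (g - g.mean(axis=1, keepdims=True)))
        z = np.where(sd[:, None] < 1e-12, 0.0, z / np.where(sd[:, None] < 1e-12, 1.0, sd[:, None]))
        pcc = (z @ z.T) / g.shape[1]
        np.fill_diagonal(pcc, np.where(sd < 1e-12, 0.0, 1.0))
        return float(np.clip(pcc, -1, 1).mean())
    f = _measure(measure, params)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += f(g[i], g[j], dates, dates)
    return total / n**2


def tas(
    group: np.ndarray,
    typical: np.ndarray,
    measure: str = "pearson",
    dates=None,
    typical_dates=None,
    params: TWDTWParams = TWDTWParams(),
) -> float:
    """Mean similarity of group members to the typical sample."""
    g = np.atleast_2d(np.asarray(group, dtype=float))
    if g.shape[0] == 0:
        raise ValueError("empty group")
    if typical_dates is None:
        typical_dates = dates
    f = _measure(measure, params)
    return float(
        np.mean([f(row, np.asarray(typical, float), dates, typical_dates) for row in g])
    )


def cross_crop_distinguishability(
    group_a: np.ndarray,
    group_b: np.ndarray,
    measure: str = "pearson",
    dates=None,
    params: TWDTWParams = TWDTWParams(),
) -> float:
    """Mean of the measure over all cross pairs (a in A, b in B).

    Low Pearson / high TWDTW distance across crops means the two crops'
    curves are easy to tell apart.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty group")
    f = _measure(measure, params)
    return float(
        np.mean([f(ra, rb, dates, dates) for ra in a for rb in b])
    )


def similarity_matrix(
    series: np.ndarray,
    ids: Sequence[str],
    measure: str = "pearson",
    dates=None,
    params: TWDTWParams = TWDTWParams(),
) -> pd.DataFrame:
    """Symmetric n x n similarity/distance matrix as a labelled DataFrame."""
    s = np.atleast_2d(np.asarray(series, dtype=float))
    n = s.shape[0]
    f = _measure(measure, params)
    out = np.zeros((n, n))
    for i in range(n):
        out[i, i] = f(s[i], s[i], dates, dates)
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = f(s[i], s[j], dates, dates)
    return pd.DataFrame(out, index=list(ids), columns=list(ids))


def gas_tas_by_scale(
    series: np.ndarray,
    labels: Sequence[str],
    levels: Sequence[int],
    measure: str = "pearson",
    dates=None,
    typical: dict[str, np.ndarray] | None = None,
    params: TWDTWParams = TWDTWParams(),
) -> pd.DataFrame:
    """GAS and TAS per (size level, crop) stratum.

    ``typical`` maps crop -> reference curve; when a crop is missing the
    stratum medoid (member with the best mean similarity to the stratum)
    is used.  Empty strata are omitted.
    """
    s = np.atleast_2d(np.asarray(series, dtype=float))
    labels = np.asarray(labels)
    levels = np.asarray(levels)
    rows = []
    for lvl in sorted(set(levels.tolist())):
        for crop in sorted(set(labels.tolist())):
            mask = (levels == lvl) & (labels == crop)
            if not mask.any():
                continue
            grp = s[mask]
            if typical is not None and crop in typical:
                ref = np.asarray(typical[crop], dtype=float)
            else:
                ref = _medoid(grp, measure, dates, params)
            rows.append(
                {
                    "size_level": lvl,
                    "crop": crop,
                    "n": int(mask.sum()),
                    "gas": gas(grp, measure, dates, params),
                    "tas": tas(grp, ref, measure, dates, dates, params),
                }
            )
    return pd.DataFrame(rows)


def _medoid(group: np.ndarray, measure, dates, params) -> np.ndarray:
    f = _measure(measure, params)
    score = [np.mean([f(a, b, dates, dates) for b in group]) for a in group]
    idx = int(np.argmax(score)) if measure == "pearson" else int(np.argmin(score))
    return group[idx]
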