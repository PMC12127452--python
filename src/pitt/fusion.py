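"""Decision-level fusion of the two probability streams and evaluation.

The time-series and texture classifiers are heterogeneous models whose
confidences are not calibrated against each other, so the framework
fuses them by a plain weighted average,

    p_fused(c) = w * p_ts(c) + (1 - w) * p_tex(c),

per branch (small parcels: stream 1, micro parcels: stream 2), with
w = 0.5 by default, and assigns each parcel the argmax class (ties
break by class enumeration order).  Evaluation is one-vs-rest
precision / recall / F1 per class and the macro-F1 (unweighted mean).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _prob_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("p_")]


def _check_simplex(df: pd.DataFrame, name: str, tol: float = 1e-6) -> None:
    p = df[_prob_cols(df)].to_numpy(dtype=float)
    if (p < -tol).any() or np.abs(p.sum(axis=1) - 1).max() > tol:
        raise ValueError(f"{name} probabilities are not simplex-valued")


def fuse(prob_a: pd.DataFrame, prob_b: pd.DataFrame, w: float = 0.5) -> pd.DataFrame:
    """Weighted average of two aligned probability tables.

    Both tables must cover the same parcel ids and classes.  The output
    is renormalized only if accumulated float drift exceeds 1e-6.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must lie in [0, 1], got {w}")
    cols = _prob_cols(prob_a)
    if cols != _prob_cols(prob_b):
        raise ValueError("probability tables disagree on classes")
    a = prob_a.set_index("parcel_id")
    b = prob_b.set_index("parcel_id")
    missing = sorted(set(a.index) ^ set(b.index))
    if missing:
        raise ValueError(f"parcel ids not shared by both streams: {missing[:10]}")
    _check_simplex(prob_a, "first stream")
    _check_simplex(prob_b, "second stream")
    b = b.loc[a.index]
    fused = w * a[cols].to_numpy(float) + (1 - w) * b[cols].to_numpy(float)
    drift = np.abs(fused.sum(axis=1) - 1.0)
    if drift.max() > 1e-6:
        fused = fused / fused.sum(axis=1, keepdims=True)
    out = pd.DataFrame(fused, columns=cols)
    out.insert(0, "parcel_id", a.index.to_numpy())
    return out


def decide(prob: pd.DataFrame) -> pd.DataFrame:
    """Argmax class per parcel; exact ties break by class column order
    and are flagged."""
    cols = _prob_cols(prob)
    p = prob[cols].to_numpy(dtype=float)
    arg = p.argmax(axis=1)
    tie = (p == p.max(axis=1, keepdims=True)).sum(axis=1) > 1
    return pd.DataFrame(
        {
            "parcel_id": prob["parcel_id"].to_numpy(),
            "class": [cols[i][2:] for i in arg],
            "tie": tie,
        }
    )


def evaluate(predictions: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """One-vs-rest confusion counts, precision/recall/F1 per class, mF1.

    ``predictions`` and ``truth`` are frames with columns parcel_id and
    class covering identical ids.  A truth class absent from the
    prediction class space is an error.
    """
    pred = predictions.set_index("parcel_id")["class"]
    true = truth.set_index("parcel_id")["class"]
    if set(pred.index) != set(true.index):
        raise ValueError("prediction and truth must cover identical parcel ids")
    true = true.loc[pred.index]
    classes = sorted(set(pred.unique()) | set(true.unique()))
    unknown = set(true.unique()) - set(classes)
    if unknown:
        raise ValueError(f"truth classes missing from prediction space: {unknown}")
    per_class = {}
    f1s = []
    n = len(pred)
    for c in classes:
        tp = int(((pred == c) & (true == c)).sum())
        fp = int(((pred == c) & (true != c)).sum())
        fn = int(((pred != c) & (true == c)).sum())
        tn = n - tp - fp - fn
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        }
        f1s.append(f1)
    return {
        "per_class": per_class,
        "mf1": float(np.mean(f1s)),
        "n": n,
        "classes": classes,
    }


def weight_sweep(
    prob_a: pd.DataFrame,
    prob_b: pd.DataFrame,
    truth: pd.DataFrame,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Evaluate the fusion over a grid of weights.

    Default grid is 0.05 to 1.0 in steps of 0.05.  Returns one row per
    weight with per-class F1 and mF1; the best row maximizes mF1.
    """
    if grid is None:
        grid = np.round(np.arange(0.05, 1.0001, 0.05), 10)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty weight grid")
    rows = []
    for w in grid:
        report = evaluate(decide(fuse(prob_a, prob_b, float(w))), truth)
        row = {"w": float(w), "mf1": report["mf1"]}
        for c, stats in report["per_class"].items():
            row[f"f1_{c}"] = stats["f1"]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["best_w"] = float(df.loc[df["mf1"].idxmax(), "w"])
    return df


def inject_complementary_noise(
    prob_a: pd.DataFrame,
    prob_b: pd.DataFrame,
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benchmark helper: degrade each stream on a complementary random
    half of the parcels (replace the row by a near-uniform vector), so
    every parcel keeps one clean stream.  Used to probe that fusing two
    partially reliable streams can beat either alone."""
    rng = np.random.default_rng(seed)
    ids = prob_a["parcel_id"].to_numpy()
    prob_b = (
        prob_b.set_index("parcel_id").loc[ids].reset_index()
    )  # align row order with prob_a
    corrupt_a = rng.random(len(ids)) < fraction
    cols = _prob_cols(prob_a)
    k = len(cols)

    def corrupted(df, mask):
        out = df.copy()
        vals = out[cols].to_numpy(dtype=float)
        noise = rng.dirichlet(np.full(k, 5.0), size=int(mask.sum()))
        vals[mask] = noise
        out[cols] = vals
        return out

    return corrupted(prob_a, corrupt_a), corrupted(prob_b, ~corrupt_a)
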