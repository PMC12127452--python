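"""KI: clustering-to-classifier time-series classification.

Small-parcel backscatter series are clustered by shape (k-Shape) into
more clusters than there are crop classes — clusters capture *types of
curves*, not crops.  High-confidence cluster members become provisional
pseudolabels, which are fine-tuned in three steps before training the
supervised classifier:

(i)   keep only members whose shape similarity to their cluster centroid
      reaches ``prob_kshape`` (default 0.97 on the (1+NCC)/2 scale);
(ii)  drop members whose raw VH level conflicts with their cluster
      (similar shape, different amplitude means a different crop);
(iii) map each surviving cluster to the crop class of its nearest
      typical phenology reference (TWDTW, Pearson fallback), discarding
      exceptionally rare clusters.

The fine-tuned pseudolabels train an InceptionTime-family classifier,
which then predicts class probabilities for parcels at every scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .features import TimeSeriesRecord, zscore
from .kshape import KShape
from .nn import InceptionTimeClassifier
from .similarity import TWDTWParams, pearson, twdtw

DEFAULT_CLASSES = ("rape", "wheat", "other")


@dataclass
class ClusterResult:
    """Output of shape clustering on a canonical (id-sorted) series set."""

    k: int
    ids: list[str]
    assignments: dict[str, int]
    centroids: np.ndarray  # (k, T) z-normalized
    similarity: dict[str, float]  # (1 + NCC)/2 to own centroid, in [0, 1]


@dataclass
class PseudoLabelEntry:
    parcel_id: str
    label: str  # crop class, or "cluster:<j>" before step (iii)
    cluster: int | None
    confidence: float
    stage: str  # kshape | ki | spice_self | kspice


@dataclass
class PseudoLabelSet:
    entries: dict[str, PseudoLabelEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return sorted(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parcel_id": e.parcel_id,
                "class": e.label,
                "confidence": e.confidence,
                "stage": e.stage,
            }
            for e in (self.entries[i] for i in self.ids())
        ]
        return pd.DataFrame(rows, columns=["parcel_id", "class", "confidence", "stage"])


@dataclass
class PhenologyReference:
    """Per-class typical phenology curves (raw backscatter level)."""

    dates: np.ndarray
    curves: dict[str, np.ndarray]

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.curves)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenologyReference":
        """Build from a long CSV frame with columns class, date, value."""
        classes = list(dict.fromkeys(df["class"]))
        dates = np.sort(df["date"].unique())
        curves = {}
        for c in classes:
            sub = df[df["class"] == c].sort_values("date")
            if not np.array_equal(sub["date"].to_numpy(), dates):
                raise ValueError(f"reference dates for class {c!r} do not align")
            curves[c] = sub["value"].to_numpy(dtype=float)
        return cls(dates=dates.astype(float), curves=curves)


def kshape_fit(
    series: dict[str, np.ndarray] | pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterResult:
    """Cluster z-normalized series by shape; canonical id-sorted order
    makes the result independent of input ordering for a fixed seed."""
    if isinstance(series, pd.DataFrame):
        series = {str(i): row.to_numpy(dtype=float) for i, row in series.iterrows()}
    ids = sorted(series)
    X = zscore(np.vstack([series[i] for i in ids]))
    model = KShape(n_clusters=k, max_iter=max_iter, random_state=seed).fit(X)
    return ClusterResult(
        k=k,
        ids=ids,
        assignments={i: int(l) for i, l in zip(ids, model.labels_)},
        centroids=model.cluster_centers_,
        similarity={i: float(s) for i, s in zip(ids, model.similarity_)},
    )


def extract_prototypes(
    cluster_result: ClusterResult, prob_kshape: float = 0.97
) -> PseudoLabelSet:
    """Step (i): keep members with similarity >= prob_kshape.

    The kept count is non-increasing in the threshold; clusters left
    empty at a high threshold are dropped with a warning.
    """
    if not (0.0 < prob_kshape <= 1.0) and prob_kshape != 0.0:
        raise ValueError("prob_kshape must lie in [0, 1]")
    out = PseudoLabelSet()
    kept_per_cluster = {j: 0 for j in range(cluster_result.k)}
    for pid in cluster_result.ids:
        sim = cluster_result.similarity[pid]
        j = cluster_result.assignments[pid]
        if sim >= prob_kshape:
            out.entries[pid] = PseudoLabelEntry(
                parcel_id=pid,
                label=f"cluster:{j}",
                cluster=j,
                confidence=sim,
                stage="kshape",
            )
            kept_per_cluster[j] += 1
    empty = [j for j, n in kept_per_cluster.items() if n == 0]
    if empty:
        warnings.warn(
            f"clusters {empty} have no members at prob_kshape={prob_kshape}; dropped",
            stacklevel=2,
        )
    return out


def filter_amplitude_conflicts(
    pseudolabels: PseudoLabelSet,
    raw_levels: dict[str, float],
    delta: float = 3.0,
) -> PseudoLabelSet:
    """Step (ii): drop members whose raw mean backscatter deviates from
    their cluster's median level by more than ``delta`` (backscatter
    units) — a shape match at the wrong amplitude is a different crop."""
    out = PseudoLabelSet()
    by_cluster: dict[int, list[str]] = {}
    for pid, e in pseudolabels.entries.items():
        by_cluster.setdefault(e.cluster, []).append(pid)
    for cluster_ids in by_cluster.values():
        med = float(np.median([raw_levels[i] for i in cluster_ids]))
        for pid in cluster_ids:
            if abs(raw_levels[pid] - med) <= delta:
                out.entries[pid] = pseudolabels.entries[pid]
    return out


def assign_crop_labels(
    pseudolabels: PseudoLabelSet,
    cluster_result: ClusterResult,
    references: PhenologyReference,
    raw_levels: dict[str, float],
    raw_stds: dict[str, float],
    dates: np.ndarray | None = None,
    min_fraction: float = 0.01,
    twdtw_params: TWDTWParams = TWDTWParams(),
    classes: tuple[str, ...] | None = None,
) -> tuple[PseudoLabelSet, dict[int, str]]:
    """Step (iii): map clusters to crops via the typical references.

    Each cluster centroid is restored to raw level (median member
    mean/std) and matched to the nearest reference by TWDTW distance;
    ties break by Pearson, then by class enumeration order.  Clusters
    holding fewer than ``min_fraction`` of all pseudolabels are dropped.

    Returns the labelled set and the cluster -> class map.
    """
    classes = tuple(classes) if classes else references.class_names
    missing = [c for c in classes if c not in references.curves]
    if missing:
        raise ValueError(f"reference set missing classes {missing}")
    dates = references.dates if dates is None else np.asarray(dates, dtype=float)
    total = len(pseudolabels)
    by_cluster: dict[int, list[str]] = {}
    for pid, e in pseudolabels.entries.items():
        by_cluster.setdefault(e.cluster, []).append(pid)
    out = PseudoLabelSet()
    cluster_classes: dict[int, str] = {}
    for j in range(cluster_result.k):
        member_ids = by_cluster.get(j, [])
        if not member_ids:
            continue
        med_level = float(np.median([raw_levels[i] for i in member_ids]))
        med_std = float(np.median([raw_stds[i] for i in member_ids]))
        centroid_raw = cluster_result.centroids[j] * med_std + med_level
        dists = np.array(
            [
                twdtw(centroid_raw, references.curves[c], dates, references.dates, twdtw_params)
                for c in classes
            ]
        )
        near = np.flatnonzero(dists <= dists.min() + 1e-9)
        if near.size > 1:  # TWDTW tie: fall back to Pearson, then class order
            corrs = [pearson(centroid_raw, references.curves[classes[i]]) for i in near]
            near = near[[int(np.argmax(corrs))]]
        cluster_classes[j] = classes[int(near[0])]
        if total > 0 and len(member_ids) < min_fraction * total:
            continue  # exceptionally rare curve type: removed
        for pid in member_ids:
            prev = pseudolabels.entries[pid]
            out.entries[pid] = PseudoLabelEntry(
                parcel_id=pid,
                label=cluster_classes[j],
                cluster=j,
                confidence=prev.confidence,
                stage="ki",
            )
    return out, cluster_classes


def kshape_label_directly(
    records: list[TimeSeriesRecord],
    references: PhenologyReference,
    k: int | None = None,
    seed: int = 0,
    twdtw_params: TWDTWParams = TWDTWParams(),
) -> pd.DataFrame:
    """Standalone k-Shape classification: cluster (default k = number of
    classes), map every cluster to the crop of its nearest typical
    reference, and label all members by their cluster's crop."""
    classes = references.class_names
    series = {r.parcel_id: np.asarray(r.values, float) for r in records}
    raw_levels = {r.parcel_id: r.raw_mean_level for r in records}
    raw_stds = {r.parcel_id: r.raw_std for r in records}
    dates = np.asarray(records[0].dates, dtype=float)
    result = kshape_fit(series, k=k or len(classes), seed=seed)
    everyone = extract_prototypes(result, 0.0)  # keep all members
    labelled, _ = assign_crop_labels(
        everyone, result, references, raw_levels, raw_stds,
        dates=dates, min_fraction=0.0, twdtw_params=twdtw_params,
    )
    ids = labelled.ids()
    return pd.DataFrame(
        {"parcel_id": ids, "class": [labelled.entries[i].label for i in ids]}
    )


def probs_frame(ids, probs: np.ndarray, classes) -> pd.DataFrame:
    """Class-probability table: one row per parcel, one p_<class> column."""
    df = pd.DataFrame(probs, columns=[f"p_{c}" for c in classes])
    df.insert(0, "parcel_id", list(ids))
    return df


class KIPipeline(BaseEstimator):
    """End-to-end KI stage as a composable estimator.

    ``fit`` consumes raw (unstandardized) small-parcel series records
    plus the typical phenology references; ``predict_proba`` emits a
    simplex over the target classes for any parcel's series, small or
    micro (the classifier is trained on small-parcel series only).

    Parameters mirror the stage knobs: cluster count (default 3x the
    number of classes), ``prob_kshape`` similarity threshold, amplitude
    tolerance ``delta`` (backscatter units), rare-cluster cut
    ``min_fraction``, classifier depth/epochs and a master seed.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        prob_kshape: float = 0.97,
        delta: float = 3.0,
        min_fraction: float = 0.01,
        twdtw_alpha: float = 0.1,
        twdtw_beta: float = 5.0,
        epochs: int = 120,
        depth: int = 3,
        n_filters: int = 8,
        n_ensemble: int = 1,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.prob_kshape = prob_kshape
        self.delta = delta
        self.min_fraction = min_fraction
        self.twdtw_alpha = twdtw_alpha
        self.twdtw_beta = twdtw_beta
        self.epochs = epochs
        self.depth = depth
        self.n_filters = n_filters
        self.n_ensemble = n_ensemble
        self.random_state = random_state

    def fit(self, records: list[TimeSeriesRecord], references: PhenologyReference):
        classes = references.class_names
        k = self.n_clusters if self.n_clusters else 3 * len(classes)
        series = {r.parcel_id: np.asarray(r.values, float) for r in records}
        raw_levels = {r.parcel_id: r.raw_mean_level for r in records}
        raw_stds = {r.parcel_id: r.raw_std for r in records}
        dates = np.asarray(records[0].dates, dtype=float)

        self.cluster_result_ = kshape_fit(series, k=k, seed=self.random_state)
        protos = extract_prototypes(self.cluster_result_, self.prob_kshape)
        protos = filter_amplitude_conflicts(protos, raw_levels, self.delta)
        self.pseudolabels_, self.cluster_classes_ = assign_crop_labels(
            protos,
            self.cluster_result_,
            references,
            raw_levels,
            raw_stds,
            dates=dates,
            min_fraction=self.min_fraction,
            twdtw_params=TWDTWParams(self.twdtw_alpha, self.twdtw_beta),
        )
        if not self.pseudolabels_.entries:
            raise ValueError("no pseudolabels survived fine-tuning")
        ids = self.pseudolabels_.ids()
        X = zscore(np.vstack([series[i] for i in ids]))
        y = np.array([self.pseudolabels_.entries[i].label for i in ids])
        if np.unique(y).size < 2:
            raise ValueError("pseudolabels collapsed to a single class")
        self.classes_ = tuple(classes)
        self.classifier_ = InceptionTimeClassifier(
            depth=self.depth,
            n_filters=self.n_filters,
            epochs=self.epochs,
            n_ensemble=self.n_ensemble,
            random_state=self.random_state,
        ).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, records: list[TimeSeriesRecord]) -> pd.DataFrame:
        ids = [r.parcel_id for r in records]
        X = zscore(np.vstack([np.asarray(r.values, float) for r in records]))
        raw = self.classifier_.predict_proba(X)
        full = np.zeros((len(ids), len(self.classes_)))
        for i, c in enumerate(self.classifier_.classes_):
            full[:, self.classes_.index(c)] = raw[:, i]
        full /= full.sum(axis=1, keepdims=True)
        return probs_frame(ids, full, self.classes_)

    def kshape_baseline(
        self, records: list[TimeSeriesRecord], references: PhenologyReference
    ) -> pd.DataFrame:
        """Plain k-Shape labelling: cluster with k = number of classes,
        read each cluster directly as a crop class (nearest typical
        reference), label every member — the standalone-clustering
        baseline the pseudolabel-plus-classifier route improves on."""
        return kshape_label_directly(
            records,
            references,
            seed=self.random_state,
            twdtw_params=TWDTWParams(self.twdtw_alpha, self.twdtw_beta),
        )
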