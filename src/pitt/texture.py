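"""k-SPICE: the high-resolution texture classification branch.

The published texture pipeline is a three-stage semi-supervised image
clustering framework (contrastive pretraining, prototype clustering,
consistency-regularised semi-supervised training).  This module keeps
those stage *contracts* at desk scale:

* ``TextureEmbedder`` — a deterministic convolutional embedding built
  from an oriented Gabor filter bank plus intensity statistics;
* ``MarginKMeans`` — prototype clustering with a per-member confidence
  (normalized margin between the nearest and second-nearest centers);
* three pseudolabel fine-tuning rules that refine texture prototypes
  with the time-series branch's predictions: (i) split prototypes mixing
  several predicted crops, (ii) drop low-similarity members, (iii) merge
  same-crop prototypes with similar textures;
* ``SemiTextureClassifier`` — a small classifier head over the
  convolutional embedding, trained on pseudolabels with a FixMatch-style
  consistency step: confident predictions on weakly augmented unlabeled
  chips supervise their strongly augmented views.

Two label-set constructions feed it: mode 1 (small parcels) converts
high-confidence time-series probabilities straight into image
pseudolabels, skipping the clustering stage; mode 2 (micro parcels)
clusters first and refines with the three rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .features import TextureChip
from .ki import PseudoLabelEntry, PseudoLabelSet, probs_frame
from .nn import Adam, Dense, ReLU, cross_entropy_grad, softmax


# ------------------------------------------------------------- embedding

def _gabor_bank(frequencies=(0.25, 0.125, 0.0625), size: int = 11, sigma: float = 3.0):
    """Oriented complex filter bank at 0/45/90/135 degrees.

    The 90 and 135 degree kernels are exact 90-degree rotations of the
    0 and 45 degree ones, so rotating a chip by 90 degrees permutes the
    orientation-energy features exactly.
    """
    half = size // 2
    u, v = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1))
    envelope = np.exp(-(u**2 + v**2) / (2 * sigma**2))
    bank = []
    for f in frequencies:
        k0 = envelope * np.exp(2j * np.pi * f * u)
        k45 = envelope * np.exp(2j * np.pi * f * (u + v) / np.sqrt(2))
        for k in (k0, k45):
            k = k - k.mean()  # remove DC so flat chips give zero energy
            bank.append(k)
            bank.append(np.rot90(k))
    return bank


_BANK = _gabor_bank()


def _embed_one(chip: np.ndarray) -> np.ndarray:
    """Filter energies pooled over the full window and over the central
    half crop (chips are centred on the parcel, so the central crop
    keeps large windows informative about the parcel itself)."""
    s = chip.shape[0]
    q = s // 4
    views = [chip, chip[q : s - q, q : s - q]]
    feats = []
    for view in views:
        gray = view.mean(axis=2).astype(float)
        for k in _BANK:
            resp = np.abs(fftconvolve(gray, k, mode="valid"))
            feats.extend([resp.mean(), resp.std()])
        gy, gx = np.gradient(gray)
        gmag = np.hypot(gx, gy)
        feats.extend([gmag.mean(), gmag.std()])
        for b in range(view.shape[2]):
            feats.extend([view[:, :, b].mean(), view[:, :, b].std()])
    return np.asarray(feats, dtype=float)


class TextureEmbedder(BaseEstimator, TransformerMixin):
    """Per-chip fixed-length feature vectors.

    ``method='handcrafted'`` (default): multi-orientation Gabor filter
    energies + gradient and intensity statistics; fully deterministic.
    ``method='random_conv'``: a seeded, untrained random convolutional
    projection (ReLU + pooled), a lightweight stochastic alternative.
    """

    def __init__(self, method: str = "handcrafted", n_random_filters: int = 32,
                 random_state: int = 0):
        self.method = method
        self.n_random_filters = n_random_filters
        self.random_state = random_state

    def fit(self, X, y=None):
        self.n_features_in_ = 1  # stateless; present for sklearn compliance
        return self

    def transform(self, X) -> np.ndarray:
        chips = _as_pixel_array(X)
        if self.method == "handcrafted":
            return np.vstack([_embed_one(c) for c in chips])
        if self.method == "random_conv":
            rng = np.random.default_rng(self.random_state)
            filt = rng.normal(size=(self.n_random_filters, 5, 5))
            filt -= filt.mean(axis=(1, 2), keepdims=True)
            out = []
            for c in chips:
                gray = c.mean(axis=2)
                feats = []
                for f in filt:
                    r = np.maximum(fftconvolve(gray, f, mode="valid"), 0.0)
                    feats.extend([r.mean(), r.max()])
                out.append(feats)
            return np.asarray(out, dtype=float)
        raise ValueError(f"unknown embedding method {self.method!r}")


def _as_pixel_array(X) -> np.ndarray:
    """Chips -> (n, s, s, 3) float array at model size; mixed sizes error."""
    if isinstance(X, np.ndarray) and X.ndim == 4:
        return X.astype(float)
    pixels = [c.model_pixels if isinstance(c, TextureChip) else np.asarray(c) for c in X]
    sizes = {p.shape for p in pixels}
    if len(sizes) > 1:
        raise ValueError(f"mixed chip sizes {sorted(sizes)}; resize chips first")
    return np.stack(pixels).astype(float)


def texture_embed(chips, method: str = "handcrafted", seed: int = 0) -> pd.DataFrame:
    """Embed chips; returns a frame indexed by parcel id."""
    ids = [c.parcel_id if isinstance(c, TextureChip) else str(i) for i, c in enumerate(chips)]
    emb = TextureEmbedder(method=method, random_state=seed).fit(None).transform(chips)
    return pd.DataFrame(emb, index=ids)


# ------------------------------------------------------------ clustering

@dataclass
class TextureProtoSet:
    """Prototype index -> member ids, member confidences, optional class."""

    members: dict[int, list[str]] = field(default_factory=dict)
    confidence: dict[str, float] = field(default_factory=dict)
    classes: dict[int, str] = field(default_factory=dict)

    def n_members(self) -> int:
        return sum(len(v) for v in self.members.values())


class MarginKMeans(BaseEstimator):
    """k-means with a normalized-margin member confidence.

    confidence = (d2 - d1) / d2 where d1, d2 are distances to the
    nearest and second-nearest centers; 1 for a member sitting on its
    center, 0 on the decision boundary.
    """

    def __init__(self, n_clusters: int = 6, random_state: int = 0, n_init: int = 10):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.n_init = n_init

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.n_clusters > X.shape[0]:
            raise ValueError(f"n_clusters={self.n_clusters} exceeds n={X.shape[0]}")
        km = KMeans(
            n_clusters=self.n_clusters,
            random_state=self.random_state,
            n_init=self.n_init,
        ).fit(X)
        self.labels_ = km.labels_
        self.cluster_centers_ = km.cluster_centers_
        d = np.linalg.norm(X[:, None, :] - km.cluster_centers_[None], axis=2)
        d.sort(axis=1)
        d1, d2 = d[:, 0], d[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            conf = np.where(d2 > 1e-12, (d2 - d1) / np.where(d2 > 1e-12, d2, 1.0), 1.0)
        self.confidence_ = np.clip(conf, 0.0, 1.0)
        return self


def texture_cluster(embedding: pd.DataFrame, k: int, seed: int = 0) -> TextureProtoSet:
    """Cluster chip embeddings into texture prototypes with confidences."""
    ids = list(embedding.index)
    X = embedding.to_numpy(dtype=float)
    mk = MarginKMeans(n_clusters=k, random_state=seed).fit(_standardize(X))
    protos = TextureProtoSet()
    for pid, lab, conf in zip(ids, mk.labels_, mk.confidence_):
        protos.members.setdefault(int(lab), []).append(pid)
        protos.confidence[pid] = float(conf)
    return protos


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return (X - mu) / np.where(sd < 1e-12, 1.0, sd)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    return float(a @ b / (na * nb))


# ------------------------------------------------- k-SPICE label building

def build_kspice1_labelset(
    prob_ki: pd.DataFrame, threshold: float = 0.99
) -> PseudoLabelSet:
    """Mode 1: high-confidence time-series predictions become image
    pseudolabels directly (no texture clustering stage).

    ``prob_ki`` has columns parcel_id, p_<class>...; parcels whose top
    probability reaches ``threshold`` are labelled with the predicted
    class, the rest form the unlabeled pool.
    """
    prob_cols = [c for c in prob_ki.columns if c.startswith("p_")]
    classes = [c[2:] for c in prob_cols]
    out = PseudoLabelSet()
    probs = prob_ki[prob_cols].to_numpy(dtype=float)
    top = probs.max(axis=1)
    arg = probs.argmax(axis=1)
    for pid, t, a in zip(prob_ki["parcel_id"], top, arg):
        if t >= threshold:
            out.entries[str(pid)] = PseudoLabelEntry(
                parcel_id=str(pid),
                label=classes[a],
                cluster=None,
                confidence=float(t),
                stage="ki",
            )
    labelled = {e.label for e in out.entries.values()}
    missing = [c for c in classes if c not in labelled]
    if missing:
        warnings.warn(
            f"no parcel reached threshold {threshold} for classes {missing}; "
            "they will be trained from the remaining classes only",
            stacklevel=2,
        )
    return out


def finetune_texture_pseudolabels(
    protos: TextureProtoSet,
    ki_classes: dict[str, str],
    embedding: pd.DataFrame,
    sim_threshold: float = 0.8,
    merge_threshold: float = 0.8,
) -> tuple[PseudoLabelSet, TextureProtoSet]:
    """Mode 2 fine-tuning of texture prototypes with time-series classes.

    (i)   a prototype containing several predicted crops is split into
          per-crop sub-prototypes;
    (ii)  members whose embedding cosine similarity to their
          sub-prototype centroid falls below ``sim_threshold`` are
          dropped;
    (iii) same-crop sub-prototypes with centroid similarity at or above
          ``merge_threshold`` are merged.

    Rules (ii) and (iii) are iterated to a joint fixed point, so the
    whole pass is idempotent.  Returns the pseudolabel set (confidence =
    clustering margin confidence) and the refined prototype set.
    """
    emb = {pid: embedding.loc[pid].to_numpy(dtype=float) for pid in embedding.index}
    # rule (i): split by predicted crop
    subs: list[tuple[str, list[str]]] = []
    for member_ids in protos.members.values():
        by_class: dict[str, list[str]] = {}
        for pid in member_ids:
            by_class.setdefault(ki_classes[pid], []).append(pid)
        subs.extend(sorted(by_class.items()))

    def centroid(ids):
        return np.mean([emb[i] for i in ids], axis=0)

    changed = True
    while changed:
        changed = False
        # rule (ii): drop low-similarity members
        kept: list[tuple[str, list[str]]] = []
        for cls, ids in subs:
            c = centroid(ids)
            survivors = [i for i in ids if _cosine(emb[i], c) >= sim_threshold]
            if len(survivors) != len(ids):
                changed = True
            if survivors:
                kept.append((cls, survivors))
        subs = kept
        # rule (iii): merge similar same-crop sub-prototypes (best pair first)
        merged = True
        while merged:
            merged = False
            best, best_sim = None, merge_threshold
            for a in range(len(subs)):
                for b in range(a + 1, len(subs)):
                    if subs[a][0] != subs[b][0]:
                        continue
                    sim = _cosine(centroid(subs[a][1]), centroid(subs[b][1]))
                    if sim >= best_sim:
                        best, best_sim = (a, b), sim
            if best:
                a, b = best
                subs[a] = (subs[a][0], subs[a][1] + subs[b][1])
                del subs[b]
                merged = changed = True

    out = PseudoLabelSet()
    refined = TextureProtoSet()
    for idx, (cls, ids) in enumerate(subs):
        refined.members[idx] = list(ids)
        refined.classes[idx] = cls
        for pid in ids:
            conf = protos.confidence.get(pid, 1.0)
            refined.confidence[pid] = conf
            out.entries[pid] = PseudoLabelEntry(
                parcel_id=pid, label=cls, cluster=idx, confidence=conf, stage="kspice"
            )
    return out, refined


# ----------------------------------------------------- augmented training

def _weak_augment(chip: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = chip
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    dy, dx = rng.integers(-2, 3, size=2)
    out = np.roll(np.roll(out, dy, axis=0), dx, axis=1)
    return out


def _strong_augment(chip: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = _weak_augment(chip, rng).copy()
    scale = rng.uniform(0.7, 1.3)
    shift = rng.uniform(-0.15, 0.15) * (np.abs(out).max() + 1e-9)
    out = out * scale + shift
    s = out.shape[0]
    cut = max(2, s // 4)
    y0 = rng.integers(0, s - cut + 1)
    x0 = rng.integers(0, s - cut + 1)
    out[y0 : y0 + cut, x0 : x0 + cut] = 0.0
    return out


class SemiTextureClassifier(BaseEstimator, ClassifierMixin):
    """Small convolutional texture classifier with FixMatch-style
    consistency training.

    The fixed Gabor filter bank acts as the convolutional feature
    extractor; a two-layer dense head is trained on pseudolabelled chips
    (weak augmentations, confidence-weighted) plus a consistency term:
    an unlabeled chip whose weakly-augmented prediction confidence
    reaches ``tau`` contributes a pseudo-target for its strongly
    augmented view.  ``tau`` > 1 switches the mechanism off, reducing
    exactly to supervised training on the label set.
    """

    def __init__(self, classes=None, tau: float = 0.95, epochs: int = 20,
                 hidden: int = 32, lr: float = 5e-3, n_views: int = 3,
                 unlabeled_weight: float = 1.0, embed_method: str = "handcrafted",
                 random_state: int = 0):
        self.classes = classes
        self.tau = tau
        self.epochs = epochs
        self.hidden = hidden
        self.lr = lr
        self.n_views = n_views
        self.unlabeled_weight = unlabeled_weight
        self.embed_method = embed_method
        self.random_state = random_state

    def fit(self, chips: list[TextureChip], labelset: PseudoLabelSet):
        if not labelset.entries:
            raise ValueError("label set is empty")
        labels = {pid: e.label for pid, e in labelset.entries.items()}
        present = sorted(set(labels.values()))
        if len(present) < 2:
            raise ValueError("label set contains a single class; cannot train")
        self.classes_ = tuple(self.classes) if self.classes else tuple(present)
        cls_index = {c: i for i, c in enumerate(self.classes_)}

        chips = sorted(chips, key=lambda c: c.parcel_id)
        pix = _as_pixel_array(chips)
        ids = [c.parcel_id for c in chips]
        rng = np.random.default_rng(self.random_state)
        embedder = TextureEmbedder(method=self.embed_method, random_state=self.random_state).fit(None)

        clean = embedder.transform(pix)
        self._mu = clean.mean(axis=0)
        sd = clean.std(axis=0)
        self._sd = np.where(sd < 1e-12, 1.0, sd)

        # precomputed augmented-view embeddings, cycled over epochs
        weak_views = [
            self._scale(embedder.transform(np.stack([_weak_augment(c, rng) for c in pix])))
            for _ in range(self.n_views)
        ]
        strong_views = [
            self._scale(embedder.transform(np.stack([_strong_augment(c, rng) for c in pix])))
            for _ in range(self.n_views)
        ]

        labeled_mask = np.array([pid in labels for pid in ids])
        y_idx = np.array([cls_index.get(labels.get(pid, present[0]), 0) for pid in ids])
        onehot = np.eye(len(self.classes_))[y_idx]
        conf = np.array([labelset.entries[pid].confidence if pid in labels else 0.0 for pid in ids])

        d = clean.shape[1]
        net_rng = np.random.default_rng(self.random_state + 1)
        self._l1 = Dense(d, self.hidden, net_rng)
        self._act = ReLU()
        self._l2 = Dense(self.hidden, len(self.classes_), net_rng)
        params = self._l1.params + self._l2.params
        opt = Adam(params, lr=self.lr)

        for epoch in range(self.epochs):
            wv = weak_views[epoch % self.n_views]
            sv = strong_views[epoch % self.n_views]
            # supervised term on weak views of labeled chips
            opt.zero_grad()
            logits = self._forward(wv[labeled_mask], train=True)
            _, dlogits = cross_entropy_grad(logits, onehot[labeled_mask], conf[labeled_mask])
            self._backward(dlogits)
            # consistency term on confident unlabeled chips
            if self.tau <= 1.0 and (~labeled_mask).any():
                probs_u = softmax(self._forward(wv[~labeled_mask], train=False))
                confident = probs_u.max(axis=1) >= self.tau
                if confident.any():
                    targets = np.eye(len(self.classes_))[probs_u.argmax(axis=1)[confident]]
                    sub = sv[~labeled_mask][confident]
                    logits_s = self._forward(sub, train=True)
                    _, dl = cross_entropy_grad(logits_s, targets)
                    frac = confident.sum() / max((~labeled_mask).sum(), 1)
                    self._backward(dl * self.unlabeled_weight * frac)
            opt.step()
        self.n_features_in_ = d
        return self

    def _scale(self, X):
        return (X - self._mu) / self._sd

    def _forward(self, X, train):
        return self._l2.forward(self._act.forward(self._l1.forward(X, train), train), train)

    def _backward(self, dlogits):
        self._l1.backward(self._act.backward(self._l2.backward(dlogits)))

    def predict_proba(self, chips) -> np.ndarray:
        check_is_fitted(self, "classes_")
        pix = _as_pixel_array(chips)
        emb = self._scale(
            TextureEmbedder(method=self.embed_method, random_state=self.random_state)
            .fit(None)
            .transform(pix)
        )
        if emb.shape[1] != self.n_features_in_:
            raise ValueError("embedding size mismatch with training")
        return softmax(self._forward(emb, train=False))

    def predict(self, chips):
        return np.array(self.classes_)[np.argmax(self.predict_proba(chips), axis=1)]


def predict_proba_texture(model: SemiTextureClassifier, chips, classes=None) -> pd.DataFrame:
    """Probability table over ``classes`` (defaults to the model's),
    zero-filling classes the model never saw."""
    ids = [c.parcel_id for c in chips]
    raw = model.predict_proba(chips)
    classes = tuple(classes) if classes else model.classes_
    full = np.zeros((len(ids), len(classes)))
    for i, c in enumerate(model.classes_):
        if c in classes:
            full[:, classes.index(c)] = raw[:, i]
    s = full.sum(axis=1, keepdims=True)
    full = full / np.where(s > 0, s, 1.0)
    return probs_frame(ids, full, classes)
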