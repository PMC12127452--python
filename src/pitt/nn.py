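"""Minimal numpy neural-network core for the two classifier heads.

Implements exactly the pieces the pipeline needs — 1-D convolutions,
max-pooling, dense layers, softmax cross-entropy and Adam — with manual
backpropagation, plus an InceptionTime-family 1-D CNN classifier:
bottleneck 1x1 convolution, parallel convolutions at three kernel
scales, a max-pool + 1x1 branch, channel concatenation, a residual
shortcut every third block, global average pooling and a softmax head.
Depth and width are configuration-scaled for desk-scale series (10
acquisition dates), and training is deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------- layers

class Layer:
    params: list  # list of [name, value, grad]

    def __init__(self):
        self.params = []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution over (N, C, T) input, odd kernel."""

    def __init__(self, in_ch, out_ch, kernel, rng):
        super().__init__()
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.kernel = kernel
        self.params = [["W", self.W, np.zeros_like(self.W)],
                       ["b", self.b, np.zeros_like(self.b)]]

    def forward(self, x, train=True):
        k = self.kernel
        pad = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        xw = sliding_window_view(xp, k, axis=2)
        if train:
            self._xw = xw
        return np.einsum("ock,nctk->not", self.W, xw, optimize=True) + self.b[None, :, None]

    def backward(self, dy):
        k = self.kernel
        pad = (k - 1) // 2
        xw = self._xw
        self.params[0][2] += np.einsum("not,nctk->ock", dy, xw, optimize=True)
        self.params[1][2] += dy.sum(axis=(0, 2))
        N, C, T = xw.shape[0], xw.shape[1], xw.shape[2]
        dxp = np.zeros((N, C, T + 2 * pad))
        for j in range(k):
            dxp[:, :, j : j + T] += np.einsum("not,oc->nct", dy, self.W[:, :, j], optimize=True)
        return dxp[:, :, pad : pad + T] if pad else dxp


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool1d(Layer):
    """Window-3, stride-1, same-size max pooling over (N, C, T)."""

    def forward(self, x, train=True):
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1)), constant_values=-np.inf)
        xw = sliding_window_view(xp, 3, axis=2)
        idx = np.argmax(xw, axis=3)
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(xw, idx[..., None], axis=3)[..., 0]

    def backward(self, dy):
        N, C, T = self._shape
        dxp = np.zeros((N, C, T + 2))
        n, c, t = np.indices((N, C, T))
        np.add.at(dxp, (n, c, t + self._idx), dy)
        return dxp[:, :, 1:-1]


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng):
        super().__init__()
        scale = np.sqrt(2.0 / in_dim)
        self.W = rng.normal(0.0, scale, size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.params = [["W", self.W, np.zeros_like(self.W)],
                       ["b", self.b, np.zeros_like(self.b)]]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.params[0][2] += self._x.T @ dy
        self.params[1][2] += dy.sum(axis=0)
        return dy @ self.W.T


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits, targets, weights=None):
    """Mean CE loss and d(loss)/d(logits); ``targets`` is (N, K) simplex
    (one-hot or soft), ``weights`` optional per-sample weights."""
    p = softmax(logits)
    n = logits.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = max(w.sum(), 1e-12)
    loss = float(-(w * (targets * np.log(p + 1e-12)).sum(axis=1)).sum() / wsum)
    grad = (p - targets) * (w / wsum)[:, None]
    return loss, grad


class Adam:
    def __init__(self, params, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p[1]) for p in params]
        self.v = [np.zeros_like(p[1]) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (name, value, grad) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p[2][...] = 0.0


# ------------------------------------------------------- inception blocks

class InceptionBlock(Layer):
    """Bottleneck + parallel convolutions (3 kernel scales) + max-pool
    branch, concatenated; output has 4 * n_filters channels."""

    def __init__(self, in_ch, n_filters, bottleneck, kernel_sizes, rng):
        super().__init__()
        self.use_bottleneck = in_ch > 1 and bottleneck > 0
        mid = bottleneck if self.use_bottleneck else in_ch
        self.bottleneck = Conv1d(in_ch, bottleneck, 1, rng) if self.use_bottleneck else None
        self.convs = [Conv1d(mid, n_filters, k, rng) for k in kernel_sizes]
        self.pool = MaxPool1d()
        self.pool_conv = Conv1d(in_ch, n_filters, 1, rng)
        for lyr in ([self.bottleneck] if self.bottleneck else []) + self.convs + [self.pool_conv]:
            self.params += lyr.params
        self._splits = None

    def forward(self, x, train=True):
        mid = self.bottleneck.forward(x, train) if self.use_bottleneck else x
        outs = [c.forward(mid, train) for c in self.convs]
        outs.append(self.pool_conv.forward(self.pool.forward(x, train), train))
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        parts = np.split(dy, self._splits, axis=1)
        dpool = self.pool.backward(self.pool_conv.backward(parts[-1]))
        dmid = sum(c.backward(p) for c, p in zip(self.convs, parts[:-1]))
        dx = self.bottleneck.backward(dmid) if self.use_bottleneck else dmid
        return dx + dpool


class InceptionTimeNet:
    """Stack of inception blocks with a residual shortcut every third
    block, global average pooling and a softmax head."""

    def __init__(self, n_classes, depth=3, n_filters=8, bottleneck=8,
                 kernel_sizes=(9, 5, 3), seed=0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.blocks = []
        self.relus = [ReLU() for _ in range(depth)]
        self.shortcuts = {}
        in_ch = 1
        res_in = 1
        for d in range(depth):
            self.blocks.append(InceptionBlock(in_ch, n_filters, bottleneck, kernel_sizes, rng))
            out_ch = 4 * n_filters
            if (d + 1) % 3 == 0:
                self.shortcuts[d] = Conv1d(res_in, out_ch, 1, rng)
                res_in = out_ch
            in_ch = out_ch
        self.head = Dense(in_ch, n_classes, rng)
        self.params = []
        for b in self.blocks:
            self.params += b.params
        for s in self.shortcuts.values():
            self.params += s.params
        self.params += self.head.params

    def forward(self, x, train=True):
        """x: (N, T) univariate series -> (N, n_classes) logits."""
        h = x[:, None, :]
        res = h
        self._cache = {"T": x.shape[1]}
        for d, block in enumerate(self.blocks):
            h = block.forward(h, train)
            if d in self.shortcuts:
                h = h + self.shortcuts[d].forward(res, train)
                h = self.relus[d].forward(h, train)
                res = h
            else:
                h = self.relus[d].forward(h, train)
        self._cache["pre_gap_channels"] = h.shape[1]
        pooled = h.mean(axis=2)
        return self.head.forward(pooled, train)

    def backward(self, dlogits):
        T = self._cache["T"]
        dpooled = self.head.backward(dlogits)
        dh = np.repeat(dpooled[:, :, None], T, axis=2) / T
        # shortcut at block d reads the activation entering block d-2;
        # its gradient re-joins the main path there
        pending: dict[int, np.ndarray] = {}
        for d in reversed(range(self.depth)):
            dh = self.relus[d].backward(dh)
            if d in self.shortcuts:
                src = max(d - 2, 0)
                g = self.shortcuts[d].backward(dh)
                pending[src] = pending.get(src, 0) + g
            dh = self.blocks[d].backward(dh)
            if d in pending:
                dh = dh + pending.pop(d)
        return dh[:, 0, :]


class InceptionTimeClassifier(BaseEstimator, ClassifierMixin):
    """Univariate time-series classifier of the InceptionTime family.

    Accepts z-normalized series of equal length as an (n, T) array.
    Desk-scale defaults (depth 3, 8 filters, single network rather than
    the canonical ensemble of 5); ``n_ensemble`` restores ensembling.

    Supports optional per-sample weights and soft targets through
    ``fit(X, y, sample_weight=...)``.
    """

    def __init__(self, depth=3, n_filters=8, bottleneck=8,
                 kernel_sizes=(9, 5, 3), epochs=120, batch_size=64,
                 lr=1e-2, n_ensemble=1, random_state=0):
        self.depth = depth
        self.n_filters = n_filters
        self.bottleneck = bottleneck
        self.kernel_sizes = kernel_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.n_ensemble = n_ensemble
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need at least 2 classes to train")
        self.classes_ = classes
        onehot = (y[:, None] == classes[None, :]).astype(float)
        self._nets = []
        for e in range(self.n_ensemble):
            net = InceptionTimeNet(
                n_classes=classes.size, depth=self.depth,
                n_filters=self.n_filters, bottleneck=self.bottleneck,
                kernel_sizes=self.kernel_sizes,
                seed=self.random_state * 1000 + e,
            )
            self._train_one(net, X, onehot, sample_weight,
                            np.random.default_rng(self.random_state * 1000 + 500 + e))
            self._nets.append(net)
        self.n_features_in_ = X.shape[1]
        return self

    def _train_one(self, net, X, targets, sample_weight, rng):
        n = X.shape[0]
        opt = Adam(net.params, lr=self.lr)
        idx = np.arange(n)
        for _ in range(self.epochs):
            rng.shuffle(idx)
            for start in range(0, n, self.batch_size):
                batch = idx[start : start + self.batch_size]
                logits = net.forward(X[batch], train=True)
                w = None if sample_weight is None else np.asarray(sample_weight)[batch]
                _, dlogits = cross_entropy_grad(logits, targets[batch], w)
                opt.zero_grad()
                net.backward(dlogits)
                opt.step()

    def predict_proba(self, X):
        check_is_fitted(self, "_nets")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"series length {X.shape[1]} != training length {self.n_features_in_}"
            )
        probs = np.mean([softmax(net.forward(X, train=False)) for net in self._nets], axis=0)
        return probs / probs.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
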