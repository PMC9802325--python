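"""Compact NumPy CNN for classifying trabecular slices, and the two-arm
experiment comparing raw micro-CT-like images against rendered extracted
networks.

Architecture (fixed topology, configurable widths): four blocks of
[3x3 convolution, stride 1, same padding -> batch normalization -> ReLU],
with a 2x2 stride-2 max pool after blocks 1-3; then two fully connected
layers and a softmax output over the two classes. Convolutions run as im2col
matrix products; training uses mini-batch Adam on the cross-entropy loss.
All randomness (weight init, shuffling, splitting) is seeded, so runs are
reproducible on a given BLAS backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .graphx import ExtractionParams, extract_network, render_network
from .phantom import LabeledCohort

# ---------------------------------------------------------------------------
# configuration and report types


@dataclass(frozen=True)
class CNNConfig:
    """Architecture + training settings.

    The topology is fixed at 4 conv blocks and 3 pool layers; ``input_size``
    must be divisible by 8 (three stride-2 pools).
    """

    input_size: int = 128
    channels_per_block: tuple[int, int, int, int] = (8, 16, 32, 64)
    fc_sizes: tuple[int, int] = (64, 2)
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 20
    train_fraction: float = 0.9
    rng_seed: int = 0

    n_conv_blocks = 4
    n_pool_layers = 3

    def __post_init__(self) -> None:
        if self.input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8 (three 2x2 pools)")
        if len(self.channels_per_block) != 4:
            raise ValueError("exactly 4 conv blocks required")
        if len(self.fc_sizes) != 2 or self.fc_sizes[1] != 2:
            raise ValueError("two FC layers required, the last of width 2")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix, accuracy, and ROC for one classifier run."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    roc_points: tuple[tuple[float, float], ...] | None
    auc: float
    arm: str = "raw_images"

    @property
    def n_test(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {
            "arm": self.arm, "tp": self.tp, "tn": self.tn, "fp": self.fp,
            "fn": self.fn, "accuracy": self.accuracy, "auc": self.auc,
            "roc_points": list(map(list, self.roc_points)) if self.roc_points else None,
        }


# ---------------------------------------------------------------------------
# layers


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (9 * c_in))  # He init
        self.w = rng.normal(0.0, scale, (c_out, c_in * 9)).astype(np.float32)
        self.b = np.zeros(c_out, np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        pad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(pad, (3, 3), axis=(2, 3))
        # (n, c, h, w, 3, 3) -> (n, h*w, c*9)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * 9)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        y = cols @ self.w.T + self.b
        if train:
            self._cache = (cols, x.shape)
        return y.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, dy: np.ndarray):
        cols, (n, c, h, w) = self._cache
        dyf = dy.reshape(n, -1, h * w).transpose(0, 2, 1)  # (n, hw, c_out)
        dw = np.einsum("npo,npk->ok", dyf, cols, optimize=True)
        db = dyf.sum(axis=(0, 1))
        dcols = dyf @ self.w  # (n, hw, c*9)
        dcols = dcols.reshape(n, h, w, c, 3, 3)
        dpad = np.zeros((n, c, h + 2, w + 2), np.float32)
        for di in range(3):
            for dj in range(3):
                dpad[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dpad[:, :, 1:-1, 1:-1], [dw, db]


class _BatchNorm:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, np.float32)
        self.beta = np.zeros(c, np.float32)
        self.run_mean = np.zeros(c, np.float32)
        self.run_var = np.ones(c, np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dy: np.ndarray):
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[:, None, None]
        dx = (inv[:, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3))[:, None, None]
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        )
        return dx, [dgamma, dbeta]


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray):
        return dy * self._mask, []


class _MaxPool2:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            mask = xr == y[:, :, :, None, :, None]
            # split ties evenly so the gradient stays exact
            self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
            self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray):
        dx = (self._mask * dy[:, :, :, None, :, None]).reshape(self._shape)
        return dx, []


class _Flatten:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray):
        return dy.reshape(self._shape), []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, (n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, np.float32)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray):
        return dy @ self.w, [dy.T @ self._x, dy.sum(axis=0)]


# ---------------------------------------------------------------------------
# model


class CNNClassifier:
    """Four-conv-block CNN with seeded initialization and Adam training."""

    def __init__(self, cfg: CNNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        ch = cfg.channels_per_block
        layers: list = []
        c_in = 1
        for i, c_out in enumerate(ch):
            layers += [_Conv3x3(c_in, c_out, rng), _BatchNorm(c_out), _ReLU()]
            if i < 3:
                layers.append(_MaxPool2())
            c_in = c_out
        side = cfg.input_size // 8
        layers.append(_Flatten())
        layers.append(_Dense(side * side * ch[3], cfg.fc_sizes[0], rng))
        layers.append(_ReLU())
        layers.append(_Dense(cfg.fc_sizes[0], cfg.fc_sizes[1], rng))
        self.layers = layers
        self.loss_trace: list[float] = []
        self._adam_state = None

    # -- introspection ------------------------------------------------------

    @property
    def parameter_count(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def describe(self) -> list[str]:
        names = {_Conv3x3: "conv3x3/s1", _BatchNorm: "batchnorm", _ReLU: "relu",
                 _MaxPool2: "maxpool2x2/s2", _Flatten: "flatten", _Dense: "fc"}
        return [names[type(l)] for l in self.layers] + ["softmax"]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"layer{i}_p{j}": p for i, l in enumerate(self.layers)
                for j, p in enumerate(l.params)}

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        data = np.load(path)
        for i, l in enumerate(self.layers):
            for j, p in enumerate(l.params):
                p[...] = data[f"layer{i}_p{j}"]

    # -- forward / training -------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities; images shaped (n, size, size) in [0,1]."""
        x = np.asarray(images, np.float32)[:, None]
        out = []
        for i in range(0, len(x), batch_size):
            logits = self._forward(x[i:i + batch_size], train=False)
            out.append(_softmax(logits))
        return np.concatenate(out)

    def fit(self, images: np.ndarray, labels: np.ndarray,
            verbose: bool = False) -> "CNNClassifier":
        """Minimize cross-entropy with Adam; appends to ``loss_trace``.

        Raises RuntimeError if the loss turns non-finite (divergence).
        """
        cfg = self.cfg
        x = np.asarray(images, np.float32)[:, None]
        y = np.asarray(labels, int)
        if len(x) == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(cfg.rng_seed + 1)
        params = [p for l in self.layers for p in l.params]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0
        b1, b2, eps = 0.9, 0.999, 1e-8
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(x))
            epoch_loss = 0.0
            for start in range(0, len(x), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                logits = self._forward(xb, train=True)
                probs = _softmax(logits)
                loss = -np.log(probs[np.arange(len(yb)), yb] + 1e-12).mean()
                if not np.isfinite(loss):
                    raise RuntimeError(f"training diverged (loss={loss}) at epoch {epoch}")
                epoch_loss += loss * len(yb)
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grads: list[np.ndarray] = []
                dy = dlogits.astype(np.float32)
                for layer in reversed(self.layers):
                    dy, g = layer.backward(dy)
                    grads = g + grads
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= b1
                    mi += (1 - b1) * g
                    vi *= b2
                    vi += (1 - b2) * g * g
                    mhat = mi / (1 - b1**t)
                    vhat = vi / (1 - b2**t)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.loss_trace.append(epoch_loss / len(x))
            if verbose:
                print(f"epoch {epoch + 1}/{cfg.epochs}  loss {self.loss_trace[-1]:.4f}")
        return self


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(cfg: CNNConfig) -> CNNClassifier:
    """Construct the (seeded) classifier for a config."""
    return CNNClassifier(cfg)


# ---------------------------------------------------------------------------
# data handling and evaluation


def split_data(labels: np.ndarray, train_fraction: float = 0.9,
               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split, deterministic under ``seed``."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < 10:
            raise ValueError(f"class {cls} has only {len(idx)} items (need >= 10)")
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def evaluate(model: CNNClassifier, images: np.ndarray, labels: np.ndarray,
             arm: str = "raw_images") -> EvalReport:
    """Confusion counts at argmax, ROC over the class-1 score, trapezoid AUC."""
    labels = np.asarray(labels, int)
    if len(labels) == 0:
        raise ValueError("empty test set")
    probs = model.predict_proba(images)
    preds = probs.argmax(axis=1)
    scores = probs[:, 1]
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    if len(np.unique(labels)) < 2:
        roc_points, auc_val = None, math.nan
    else:
        fpr, tpr, _ = _roc_curve(labels, scores, drop_intermediate=False)
        roc_points = tuple(zip(fpr.tolist(), tpr.tolist()))
        auc_val = float(_trapezoid_auc(fpr, tpr))
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn,
                      accuracy=(tp + tn) / len(labels),
                      roc_points=roc_points, auc=auc_val, arm=arm)


def _resize(pixels: np.ndarray, size: int) -> np.ndarray:
    from skimage.transform import resize as _sk_resize
    if pixels.shape == (size, size):
        return pixels.astype(np.float32)
    return _sk_resize(pixels, (size, size), anti_aliasing=True).astype(np.float32)


def cohort_arrays(cohort: LabeledCohort, cfg: CNNConfig,
                  extraction: ExtractionParams | None = None):
    """(raw, rendered-network, labels) arrays for the two-arm experiment."""
    size = cfg.input_size
    raw = np.stack([_resize(img.pixels, size) for img in cohort.images])
    nets = None
    if extraction is not None:
        rendered = []
        for img in cohort.images:
            g = extract_network(img, extraction)
            rendered.append(_resize(render_network(g, img.shape).pixels, size))
        nets = np.stack(rendered)
    return raw, nets, np.asarray(cohort.labels, int)


def run_two_arm_experiment(cohort: LabeledCohort, extraction: ExtractionParams,
                           cfg: CNNConfig) -> tuple[EvalReport, EvalReport]:
    """Train/evaluate once on raw slices and once on rendered networks.

    Both arms share the identical stratified split and config (including
    seeds); only the input encoding differs.
    """
    raw, nets, labels = cohort_arrays(cohort, cfg, extraction)
    train_idx, test_idx = split_data(labels, cfg.train_fraction, seed=cfg.rng_seed)
    reports = []
    for arm, data in (("raw_images", raw), ("extracted_networks", nets)):
        model = build_model(cfg)
        model.fit(data[train_idx], labels[train_idx])
        reports.append(evaluate(model, data[test_idx], labels[test_idx], arm=arm))
    return reports[0], reports[1]
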