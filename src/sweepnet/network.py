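"""Convolutional network for sweep classification, implemented in NumPy.

The architecture family is small and fixed in shape: a stack of 2-D
convolutions (stride 1, no zero-padding, ReLU) each followed by 2x2 max
pooling, then an optional fully-connected ReLU layer, and a softmax output
over the classes.  Training minimizes the cross-entropy between the softmax
output and a (possibly soft) target distribution with the Adam optimizer.

Everything runs on plain NumPy arrays: forward and backward passes are
expressed as im2col matrix products, so a desk-scale experiment (a few
thousand 64x64 images) trains in minutes on one CPU core, deterministically
for a fixed seed.  ``SweepCNN`` exposes the scikit-learn estimator API and
composes with sklearn model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NetworkSpec",
    "TrainingRun",
    "layer_shape_plan",
    "cross_entropy",
    "SweepCNN",
    "evaluate",
    "confusion_matrix",
]

_EPS = 1e-7


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description.

    conv_filters
        Filter count per convolutional layer, e.g. (32, 32, 32) or
        (32, 64, 128).  Each convolution uses ``kernel`` x ``kernel``
        filters with stride 1 and no zero-padding, followed by a
        ``pool`` x ``pool`` max-pooling layer (pool=1 disables pooling).
    dense_units
        Units of the fully-connected hidden layer, or None to omit it
        (recommended for double-sorted images, whose spatial feature
        layout survives to the last feature map).
    """

    conv_filters: tuple[int, ...] = (32, 32, 32)
    kernel: int = 3
    pool: int = 2
    dense_units: int | None = 64
    n_outputs: int = 2
    batch_size: int = 32

    def __post_init__(self) -> None:
        if not self.conv_filters or any(f < 1 for f in self.conv_filters):
            raise ValueError("conv_filters must be a non-empty tuple of counts >= 1")
        if self.kernel < 1 or self.pool < 1:
            raise ValueError("kernel and pool sizes must be >= 1")
        if self.dense_units is not None and self.dense_units < 1:
            raise ValueError("dense_units must be >= 1 or None")
        if self.n_outputs < 2:
            raise ValueError("n_outputs must be >= 2")


def layer_shape_plan(
    spec: NetworkSpec, input_height: int, input_width: int
) -> list[tuple[str, tuple[int, int, int]]]:
    """Per-layer output shapes (height, width, channels) plus the flat size.

    Valid convolution shrinks each side by kernel-1; max pooling divides it
    by the pool size (floor).  Raises if any layer's output would vanish.
    The final entry is ``("flatten", (1, 1, n_features))``.
    """
    h, w, c = input_height, input_width, 1
    plan: list[tuple[str, tuple[int, int, int]]] = [("input", (h, w, c))]
    for li, f in enumerate(spec.conv_filters):
        h, w = h - spec.kernel + 1, w - spec.kernel + 1
        if h < 1 or w < 1:
            raise ValueError(
                f"conv layer {li}: output {h}x{w} below 1x1 "
                f"(input too small for kernel {spec.kernel})"
            )
        c = f
        plan.append((f"conv{li}", (h, w, c)))
        if spec.pool > 1:
            h, w = h // spec.pool, w // spec.pool
            if h < 1 or w < 1:
                raise ValueError(f"pool after conv layer {li}: output below 1x1")
            plan.append((f"pool{li}", (h, w, c)))
    plan.append(("flatten", (1, 1, h * w * c)))
    return plan


def cross_entropy(predicted: np.ndarray, target: np.ndarray) -> float:
    """Cross-entropy -sum_k target_k log(predicted_k) between distributions.

    Predicted entries are clipped to [eps, 1] before the log.  The value is
    bounded below by the target's entropy, with equality iff the
    distributions coincide.
    """
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if predicted.shape != target.shape:
        raise ValueError("predicted and target must have equal shape")
    p = np.clip(predicted, _EPS, 1.0)
    return float(-np.sum(target * np.log(p), axis=-1).mean())


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# im2col convolution primitives


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, P, C*k*k) patch matrix for valid convolution."""
    b = x.shape[0]
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (B, C, Ho, Wo, k, k)
    win = win.transpose(0, 2, 3, 1, 4, 5)  # (B, Ho, Wo, C, k, k)
    ho, wo = win.shape[1], win.shape[2]
    return np.ascontiguousarray(win).reshape(b, ho * wo, -1), ho, wo


def _col_index_map(c: int, h: int, w: int, ho: int, wo: int, k: int) -> np.ndarray:
    """Flat input indices (P, C*k*k) matching the _im2col patch layout."""
    base = (np.arange(ho)[:, None] * w + np.arange(wo)[None, :]).reshape(-1, 1)
    off = (
        np.arange(c)[:, None, None] * h * w
        + np.arange(k)[None, :, None] * w
        + np.arange(k)[None, None, :]
    ).reshape(1, -1)
    return base + off


class _Conv:
    def __init__(self, c_in: int, f: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, f)).astype(
            np.float32
        )
        self.b = np.zeros(f, dtype=np.float32)
        self.c_in, self.f, self.k = c_in, f, k

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.k)
        self._cols, self._xshape, self._howo = cols, x.shape, (ho, wo)
        out = cols @ self.w + self.b  # (B, P, F)
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.f, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, _, ho, wo = dout.shape
        dmat = dout.reshape(b, self.f, ho * wo).transpose(0, 2, 1)  # (B, P, F)
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        dmat2 = np.ascontiguousarray(dmat).reshape(-1, self.f)
        self.dw = (cols2.T @ dmat2).astype(np.float32)
        self.db = dmat2.sum(axis=0).astype(np.float32)
        dcols = dmat @ self.w.T  # (B, P, C*k*k)
        _, c, h, w = self._xshape
        idx = _col_index_map(c, h, w, ho, wo, self.k)
        chw = c * h * w
        flat = (idx[None] + (np.arange(b) * chw)[:, None, None]).ravel()
        dx = np.bincount(flat, weights=dcols.ravel(), minlength=b * chw)
        return dx.reshape(b, c, h, w).astype(np.float32)

    @property
    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    params: list = []


class _MaxPool:
    def __init__(self, size: int):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.size
        b, c, h, w = x.shape
        ph, pw = h // s, w // s
        xr = x[:, :, : ph * s, : pw * s].reshape(b, c, ph, s, pw, s)
        out = xr.max(axis=(3, 5))
        # tie-aware mask: gradient is split equally among maximal entries
        mask = xr == out[:, :, :, None, :, None]
        self._mask = mask
        self._cnt = mask.sum(axis=(3, 5))
        self._xshape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self.size
        b, c, h, w = self._xshape
        ph, pw = h // s, w // s
        g = (dout / self._cnt)[:, :, :, None, :, None] * self._mask
        dx = np.zeros((b, c, h, w), dtype=np.float32)
        dx[:, :, : ph * s, : pw * s] = g.reshape(b, c, ph * s, pw * s)
        return dx

    params: list = []


class _Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    params: list = []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(
            np.float32
        )
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = (self._x.T @ dout).astype(np.float32)
        self.db = dout.sum(axis=0).astype(np.float32)
        return (dout @ self.w.T).astype(np.float32)

    @property
    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, layers: Sequence) -> None:
        self.t += 1
        for li, layer in enumerate(layers):
            for pi, (name, p, gname) in enumerate(layer.params):
                g = getattr(layer, gname)
                key = (li, pi)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[key]
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g * g
                self.state[key] = (m, v)
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


@dataclass
class TrainingRun:
    """Record of one training invocation.

    ``history`` holds one row per logged iteration with train/validation
    loss and accuracy; ``schedule`` is ``"epochs"`` (multi-pass) or
    ``"one-pass"`` (each example visited exactly once, in chunks).
    """

    history: pd.DataFrame
    seed: int | None
    schedule: str
    spec: NetworkSpec
    confusion: np.ndarray | None = None

    def to_csv(self, path: str) -> None:
        self.history.to_csv(path, index=False)
        sidecar = {
            "seed": self.seed,
            "schedule": self.schedule,
            "spec": {
                "conv_filters": list(self.spec.conv_filters),
                "kernel": self.spec.kernel,
                "pool": self.spec.pool,
                "dense_units": self.spec.dense_units,
                "n_outputs": self.spec.n_outputs,
                "batch_size": self.spec.batch_size,
            },
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


class SweepCNN(BaseEstimator, ClassifierMixin):
    """CNN classifier over haplotype images, scikit-learn style.

    Parameters
    ----------
    conv_filters, kernel_size, pool_size, dense_units
        Architecture; see :class:`NetworkSpec`.
    learning_rate, n_epochs, batch_size
        Adam learning rate and training schedule.
    schedule
        ``"epochs"`` re-visits the training set ``n_epochs`` times;
        ``"one-pass"`` partitions it into ``n_chunks`` chunks, each visited
        exactly once (the hybrid simulation-on-the-fly surrogate for a
        pre-generated training set).
    random_state
        Seeds weight initialization and batch shuffling; runs are
        bit-reproducible on a single thread.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    layers_ : list
        The trained layer stack.
    training_run_ : TrainingRun
        Loss/accuracy history.
    """

    def __init__(
        self,
        conv_filters: tuple[int, ...] = (32, 32, 32),
        kernel_size: int = 3,
        pool_size: int = 2,
        dense_units: int | None = 64,
        learning_rate: float = 1e-3,
        n_epochs: int = 5,
        batch_size: int = 32,
        schedule: str = "epochs",
        n_chunks: int = 4,
        random_state: int | None = 0,
        verbose: int = 0,
    ):
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.schedule = schedule
        self.n_chunks = n_chunks
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------

    def _build(self, h: int, w: int, n_classes: int, rng: np.random.Generator):
        spec = NetworkSpec(
            conv_filters=tuple(self.conv_filters),
            kernel=self.kernel_size,
            pool=self.pool_size,
            dense_units=self.dense_units,
            n_outputs=n_classes,
            batch_size=self.batch_size,
        )
        plan = layer_shape_plan(spec, h, w)
        layers: list = []
        c_in = 1
        for f in spec.conv_filters:
            layers.append(_Conv(c_in, f, spec.kernel, rng))
            layers.append(_ReLU())
            if spec.pool > 1:
                layers.append(_MaxPool(spec.pool))
            c_in = f
        layers.append(_Flatten())
        n_flat = plan[-1][1][2]
        if spec.dense_units is not None:
            layers.append(_Dense(n_flat, spec.dense_units, rng))
            layers.append(_ReLU())
            n_flat = spec.dense_units
        layers.append(_Dense(n_flat, n_classes, rng))
        return spec, plan, layers

    def _forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers_:
            x = layer.forward(x)
        return x

    @staticmethod
    def _as_targets(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
        """Hard labels -> one-hot rows; 2-D input is taken as distributions."""
        y = np.asarray(y)
        if y.ndim == 2:
            return y.astype(np.float32)
        idx = np.searchsorted(classes, y)
        t = np.zeros((y.shape[0], classes.size), dtype=np.float32)
        t[np.arange(y.shape[0]), idx] = 1.0
        return t

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        validation_data: tuple[np.ndarray, np.ndarray] | None = None,
        batch_callback: Callable[[np.ndarray], None] | None = None,
    ) -> "SweepCNN":
        """Train on images ``X`` (N, H, W) with labels ``y``.

        ``y`` may be integer class labels or an (N, K) matrix of target
        distributions (categorical, Gaussian or perturbed).  An optional
        ``validation_data=(Xv, yv)`` pair is scored after every epoch or
        chunk.  ``batch_callback`` receives the example indices of every
        minibatch (used to verify one-pass scheduling).
        """
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("X must be (N, H, W)")
        y = np.asarray(y)
        if y.ndim == 2:
            self.classes_ = np.arange(y.shape[1])
            hard = y.argmax(axis=1)
        else:
            self.classes_ = np.unique(y)
            hard = y
        targets = self._as_targets(y, self.classes_)
        n, h, w = X.shape
        rng = np.random.default_rng(self.random_state)
        spec, plan, layers = self._build(h, w, len(self.classes_), rng)
        self.spec_, self.shape_plan_, self.layers_ = spec, plan, layers
        self.input_shape_ = (h, w)

        opt = _Adam(self.learning_rate)
        history: list[dict] = []

        if self.schedule == "epochs":
            passes = [
                ("epoch", e, rng.permutation(n)) for e in range(self.n_epochs)
            ]
        elif self.schedule == "one-pass":
            perm = rng.permutation(n)
            chunks = np.array_split(perm, self.n_chunks)
            passes = [("chunk", c, chunk) for c, chunk in enumerate(chunks)]
        else:
            raise ValueError(f"unknown schedule {self.schedule!r}")

        iteration = 0
        for kind, number, order in passes:
            losses, accs = [], []
            for start in range(0, order.size, self.batch_size):
                idx = order[start : start + self.batch_size]
                if batch_callback is not None:
                    batch_callback(idx)
                xb = X[idx][:, None, :, :]
                tb = targets[idx]
                logits = self._forward(xb)
                probs = _softmax(logits)
                loss = cross_entropy(probs, tb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at iteration {iteration}"
                    )
                losses.append(loss)
                accs.append(float((probs.argmax(1) == hard[idx]).mean()))
                grad = (probs - tb).astype(np.float32) / xb.shape[0]
                for layer in reversed(self.layers_):
                    grad = layer.backward(grad)
                opt.step(self.layers_)
                iteration += 1
            row = {
                "iteration": iteration,
                kind: number,
                "train_loss": float(np.mean(losses)),
                "train_acc": float(np.mean(accs)),
                "val_loss": np.nan,
                "val_acc": np.nan,
            }
            if validation_data is not None:
                xv, yv = validation_data
                pv = self.predict_proba(np.asarray(xv, dtype=np.float32))
                tv = self._as_targets(np.asarray(yv), self.classes_)
                hv = tv.argmax(axis=1)
                row["val_loss"] = cross_entropy(pv, tv)
                row["val_acc"] = float((pv.argmax(1) == hv).mean())
            if self.verbose:
                print(
                    f"{kind} {number}: loss={row['train_loss']:.4f} "
                    f"acc={row['train_acc']:.4f} val_acc={row['val_acc']:.4f}"
                )
            history.append(row)

        self.training_run_ = TrainingRun(
            history=pd.DataFrame(history),
            seed=self.random_state,
            schedule=self.schedule,
            spec=spec,
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, one valid distribution per image."""
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=np.float32)
        out = []
        for start in range(0, X.shape[0], max(1, self.batch_size)):
            xb = X[start : start + self.batch_size][:, None, :, :]
            out.append(_softmax(self._forward(xb)))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())

    # ------------------------------------------------------------------

    def save(self, path: str) -> None:
        """Save weights and architecture to a .npz checkpoint."""
        check_is_fitted(self, "layers_")
        arrays: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self.layers_):
            for name, p, _ in layer.params:
                arrays[f"layer{li}_{name}"] = p
        arrays["classes"] = self.classes_
        meta = dict(self.get_params())
        meta["input_shape"] = list(self.input_shape_)
        meta["conv_filters"] = list(meta["conv_filters"])
        arrays["meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "SweepCNN":
        """Restore a checkpoint written by :meth:`save`."""
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["meta"]).decode())
        input_shape = tuple(meta.pop("input_shape"))
        meta["conv_filters"] = tuple(meta["conv_filters"])
        model = cls(**meta)
        classes = data["classes"]
        rng = np.random.default_rng(0)
        spec, plan, layers = model._build(*input_shape, len(classes), rng)
        model.spec_, model.shape_plan_, model.layers_ = spec, plan, layers
        model.classes_ = classes
        model.input_shape_ = input_shape
        for li, layer in enumerate(layers):
            for name, p, _ in layer.params:
                p[...] = data[f"layer{li}_{name}"]
        return model


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> np.ndarray:
    """K x K count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def evaluate(model: SweepCNN, X: np.ndarray, y: np.ndarray) -> dict:
    """Confusion matrix, row-normalized rates and overall accuracy."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty test set")
    pred = model.predict(X)
    classes = model.classes_
    k = classes.size
    ti = np.searchsorted(classes, y)
    pi = np.searchsorted(classes, pred)
    cm = confusion_matrix(ti, pi, k)
    row_sums = cm.sum(axis=1, keepdims=True)
    rates = np.divide(cm, row_sums, out=np.zeros_like(cm, dtype=float),
                      where=row_sums > 0)
    return {
        "confusion": cm,
        "rates": rates,
        "accuracy": float(np.trace(cm) / cm.sum()),
        "classes": classes,
    }
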