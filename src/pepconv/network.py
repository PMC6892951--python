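"""A small per-allele convolutional classifier for peptide-MHC I binding.

Architecture (faithful preset): two 1-D convolution layers of 20 filters
each over the 15-position axis (feature rows enter as channels), each
followed by ReLU and max pooling, then a dense ReLU layer with dropout and
a single sigmoid output — the probability that the peptide binds the
allele.  Training minimizes binary cross-entropy with an Adam optimizer,
mini-batches, and early stopping on an internal validation split.

The network is implemented directly in numpy (forward and backward passes)
so that training is exactly reproducible under a fixed seed: identical
seed, data and configuration give an identical trajectory.

``PeptideConvNet`` follows the scikit-learn estimator protocol: it is
constructed with hyperparameters only, ``fit(X, y)`` accepts a sequence of
raw peptide strings (length 8-15) plus binary labels, and fitted state
lives in trailing-underscore attributes.  It therefore composes with
``sklearn.base.clone`` and model-selection utilities that accept string
features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

from .encoders import ENCODING_MODES, ENCODING_SHAPES, encode_batch

N_POSITIONS = 15


class DegenerateDataError(ValueError):
    """Training data does not contain both classes (or is too small)."""


class ConfigurationError(ValueError):
    """Kernel/pool sizes incompatible with the 15-position axis."""


class TrainingFailure(RuntimeError):
    """Loss became non-finite during optimization."""


# ---------------------------------------------------------------------------
# layers: plain-numpy forward/backward pairs


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x: (n, c, L); w: (f, c, k); returns (n, f, L-k+1) and the window cache."""
    k = w.shape[2]
    windows = sliding_window_view(x, k, axis=2)  # (n, c, L-k+1, k)
    out = np.einsum("nclk,fck->nfl", windows, w, optimize=True) + b[None, :, None]
    return out, windows


def _conv1d_backward(dout: np.ndarray, windows: np.ndarray, w: np.ndarray, in_len: int):
    dw = np.einsum("nfl,nclk->fck", dout, windows, optimize=True)
    db = dout.sum(axis=(0, 2))
    n, _, l_out = dout.shape
    c, k = w.shape[1], w.shape[2]
    dx = np.zeros((n, c, in_len))
    for j in range(k):
        dx[:, :, j : j + l_out] += np.einsum("nfl,fc->ncl", dout, w[:, :, j], optimize=True)
    return dx, dw, db


def _maxpool_forward(x: np.ndarray, size: int):
    """Non-overlapping max pooling along the last axis, remainder dropped."""
    n, c, L = x.shape
    l_out = L // size
    xv = x[:, :, : l_out * size].reshape(n, c, l_out, size)
    idx = xv.argmax(axis=3)
    out = np.take_along_axis(xv, idx[..., None], axis=3)[..., 0]
    return out, (idx, x.shape)


def _maxpool_backward(dout: np.ndarray, cache, size: int):
    idx, in_shape = cache
    n, c, L = in_shape
    l_out = dout.shape[2]
    dxv = np.zeros((n, c, l_out, size))
    np.put_along_axis(dxv, idx[..., None], dout[..., None], axis=3)
    dx = np.zeros(in_shape)
    dx[:, :, : l_out * size] = dxv.reshape(n, c, l_out * size)
    return dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_from_logits(z: np.ndarray, y: np.ndarray) -> float:
    # mean(softplus(z) - y z), computed stably
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


@dataclass
class _Params:
    """Weight container for the two-conv + dense + output head."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    wd: np.ndarray
    bd: np.ndarray
    wo: np.ndarray
    bo: np.ndarray

    def as_list(self):
        return [self.w1, self.b1, self.w2, self.b2, self.wd, self.bd, self.wo, self.bo]

    def copy(self) -> "_Params":
        return _Params(*[p.copy() for p in self.as_list()])


class _Adam:
    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class PeptideConvNet(BaseEstimator, ClassifierMixin):
    """Per-allele convolutional binding classifier over encoded 15mer frames.

    Parameters
    ----------
    encoding_mode : {"chemical", "substitution", "stacked"}
        Feature view fed to the network: the 4x15 chemical-property matrix
        (default), the transposed 15x21 substitution encoding, or both
        stacked to 25x15.
    n_filters : int
        Filters per convolution layer (20 in the faithful preset).
    kernel_size, pool_size : int
        1-D convolution kernel and max-pool width along the position axis.
    dense_units : int
        Width of the dense ReLU layer before the output unit.
    dropout : float
        Dropout probability on the dense activations during training.
    learning_rate, batch_size, max_epochs : Adam step size, mini-batch
        size, and epoch cap.
    patience : int
        Early-stopping patience (epochs without validation-loss improvement);
        the best-validation weights are restored.
    validation_fraction : float
        Fraction of the training data held out internally for early stopping.
    standardize : bool
        Standardize channels over the training set before fitting (off by
        default; raw encoded values are the faithful input).
    threshold : float
        Probability cut used by :meth:`predict`.
    random_state : int
        Seed for weight initialization, batching and dropout.
    """

    def __init__(
        self,
        encoding_mode: str = "chemical",
        n_filters: int = 20,
        kernel_size: int = 3,
        pool_size: int = 2,
        dense_units: int = 64,
        dropout: float = 0.25,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 100,
        patience: int = 10,
        validation_fraction: float = 0.1,
        standardize: bool = False,
        threshold: float = 0.5,
        random_state: int = 42,
    ):
        self.encoding_mode = encoding_mode
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dense_units = dense_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.standardize = standardize
        self.threshold = threshold
        self.random_state = random_state

    # -- architecture ------------------------------------------------------

    def _spatial_extents(self) -> tuple[int, int, int, int]:
        """Lengths after conv1, pool1, conv2, pool2; validates the config."""
        if self.encoding_mode not in ENCODING_MODES:
            raise ConfigurationError(
                f"unknown encoding mode {self.encoding_mode!r}; expected one of {ENCODING_MODES}"
            )
        if self.kernel_size < 1 or self.pool_size < 1:
            raise ConfigurationError("kernel_size and pool_size must be >= 1")
        l1 = N_POSITIONS - self.kernel_size + 1
        if l1 < 1:
            raise ConfigurationError(
                f"kernel_size {self.kernel_size} leaves no positions after conv1"
            )
        p1 = l1 // self.pool_size
        if p1 < 1:
            raise ConfigurationError(
                f"pool_size {self.pool_size} too large for extent {l1} after conv1"
            )
        l2 = p1 - self.kernel_size + 1
        if l2 < 1:
            raise ConfigurationError(
                f"kernel_size {self.kernel_size} leaves no positions after conv2 (extent {p1})"
            )
        p2 = l2 // self.pool_size
        if p2 < 1:
            raise ConfigurationError(
                f"pool_size {self.pool_size} too large for extent {l2} after conv2"
            )
        return l1, p1, l2, p2

    def _init_params(self, rng: np.random.Generator) -> _Params:
        c_in = ENCODING_SHAPES[self.encoding_mode][0]
        _, _, _, p2 = self._spatial_extents()
        f, k, d = self.n_filters, self.kernel_size, self.dense_units
        flat = f * p2

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        return _Params(
            w1=he((f, c_in, k), c_in * k),
            b1=np.zeros(f),
            w2=he((f, f, k), f * k),
            b2=np.zeros(f),
            wd=he((flat, d), flat),
            bd=np.zeros(d),
            wo=he((d, 1), d),
            bo=np.zeros(1),
        )

    def _forward(self, x: np.ndarray, params: _Params, *, train: bool = False, rng=None):
        p = params
        z1, win1 = _conv1d_forward(x, p.w1, p.b1)
        a1 = np.maximum(z1, 0.0)
        m1, cache1 = _maxpool_forward(a1, self.pool_size)
        z2, win2 = _conv1d_forward(m1, p.w2, p.b2)
        a2 = np.maximum(z2, 0.0)
        m2, cache2 = _maxpool_forward(a2, self.pool_size)
        flat = m2.reshape(m2.shape[0], -1)
        zd = flat @ p.wd + p.bd
        ad = np.maximum(zd, 0.0)
        if train and self.dropout > 0:
            mask = (rng.random(ad.shape) >= self.dropout) / (1.0 - self.dropout)
            ad = ad * mask
        else:
            mask = None
        logits = (ad @ p.wo + p.bo).ravel()
        cache = (x, z1, win1, a1, cache1, m1, z2, win2, a2, cache2, m2, flat, zd, ad, mask)
        return logits, cache

    def _backward(self, dlogits: np.ndarray, params: _Params, cache):
        p = params
        (x, z1, win1, a1, cache1, m1, z2, win2, a2, cache2, m2, flat, zd, ad, mask) = cache
        n = x.shape[0]
        dlog = dlogits[:, None]
        dwo = ad.T @ dlog
        dbo = dlog.sum(axis=0)
        dad = dlog @ p.wo.T
        if mask is not None:
            dad = dad * mask
        dzd = dad * (zd > 0)
        dwd = flat.T @ dzd
        dbd = dzd.sum(axis=0)
        dflat = dzd @ p.wd.T
        dm2 = dflat.reshape(m2.shape)
        da2 = _maxpool_backward(dm2, cache2, self.pool_size)
        dz2 = da2 * (z2 > 0)
        dm1, dw2, db2 = _conv1d_backward(dz2, win2, p.w2, m1.shape[2])
        da1 = _maxpool_backward(dm1, cache1, self.pool_size)
        dz1 = da1 * (z1 > 0)
        _, dw1, db1 = _conv1d_backward(dz1, win1, p.w1, x.shape[2])
        return [dw1, db1, dw2, db2, dwd, dbd, dwo, dbo]

    # -- sklearn API -------------------------------------------------------

    def _encode(self, X: Sequence[str]) -> np.ndarray:
        stack = encode_batch(list(X), self.encoding_mode)
        if getattr(self, "channel_mean_", None) is not None:
            stack = (stack - self.channel_mean_[None, :, None]) / self.channel_std_[
                None, :, None
            ]
        return stack

    def fit(self, X: Sequence[str], y: Sequence[int]) -> "PeptideConvNet":
        """Train on raw peptide strings ``X`` and binary labels ``y``."""
        self._spatial_extents()  # fail fast on bad geometry
        y_arr = np.asarray(y, dtype=np.float64).ravel()
        X = list(X)
        if len(X) != len(y_arr):
            raise ValueError(f"X and y disagree: {len(X)} vs {len(y_arr)}")
        classes = np.unique(y_arr)
        if len(X) < 2 or len(classes) < 2:
            raise DegenerateDataError(
                "training requires at least 2 examples with both classes present "
                f"(got n={len(X)}, classes={classes.tolist()})"
            )
        if not set(classes.tolist()) <= {0.0, 1.0}:
            raise ValueError(f"labels must be binary 0/1, got {classes.tolist()}")

        self.channel_mean_ = None
        self.channel_std_ = None
        stack = encode_batch(X, self.encoding_mode)
        if self.standardize:
            mean = stack.mean(axis=(0, 2))
            sd = stack.std(axis=(0, 2))
            self.channel_mean_ = mean
            self.channel_std_ = np.where(sd > 0, sd, 1.0)
            stack = (stack - mean[None, :, None]) / self.channel_std_[None, :, None]

        rng = np.random.default_rng(self.random_state)
        params = self._init_params(rng)
        opt = _Adam([p.shape for p in params.as_list()], lr=self.learning_rate)

        n = len(X)
        order = rng.permutation(n)
        n_val = int(round(self.validation_fraction * n)) if self.patience > 0 else 0
        # keep both classes in the training portion
        if n_val > 0:
            val_idx, tr_idx = order[:n_val], order[n_val:]
            if len(np.unique(y_arr[tr_idx])) < 2 or len(tr_idx) == 0:
                n_val = 0
        if n_val == 0:
            tr_idx, val_idx = order, np.empty(0, dtype=int)
        x_tr, y_tr = stack[tr_idx], y_arr[tr_idx]
        x_val, y_val = stack[val_idx], y_arr[val_idx]

        best_val = np.inf
        best_params = params.copy()
        stale = 0
        history: list[dict[str, float]] = []
        epochs_run = 0
        for epoch in range(self.max_epochs):
            epochs_run = epoch + 1
            perm = rng.permutation(len(x_tr))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(perm), self.batch_size):
                idx = perm[start : start + self.batch_size]
                xb, yb = x_tr[idx], y_tr[idx]
                logits, cache = self._forward(xb, params, train=True, rng=rng)
                loss = _bce_from_logits(logits, yb)
                if not np.isfinite(loss):
                    raise TrainingFailure(
                        f"non-finite loss at epoch {epoch + 1}: {loss} "
                        f"(lr={self.learning_rate}, batch={self.batch_size})"
                    )
                dlogits = (_sigmoid(logits) - yb) / len(yb)
                grads = self._backward(dlogits, params, cache)
                opt.step(params.as_list(), grads)
                epoch_loss += loss
                n_batches += 1
            record = {"epoch": epoch + 1, "train_loss": epoch_loss / max(n_batches, 1)}
            if n_val > 0:
                val_logits, _ = self._forward(x_val, params)
                val_loss = _bce_from_logits(val_logits, y_val)
                record["val_loss"] = val_loss
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_params = params.copy()
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        history.append(record)
                        break
            history.append(record)
        if n_val > 0:
            params = best_params

        self.params_ = params
        self.classes_ = np.array([0, 1])
        self.history_ = history
        self.n_examples_ = n
        self.epochs_run_ = epochs_run
        self.final_loss_ = history[-1]["train_loss"] if history else np.nan
        return self

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        """Class probabilities, shape (n, 2); column 1 is P(binder)."""
        self._check_fitted()
        p1 = self.decision_scores(X)
        return np.column_stack([1.0 - p1, p1])

    def decision_scores(self, X: Sequence[str]) -> np.ndarray:
        """P(binder) per peptide, order-preserving, deterministic."""
        self._check_fitted()
        stack = self._encode(list(X))
        if len(stack) == 0:
            return np.empty(0)
        logits, _ = self._forward(stack, self.params_)
        return _sigmoid(logits)

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("this PeptideConvNet instance is not fitted yet")

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path, allele: str | None = None) -> None:
        """Write a model bundle: config JSON + weight blob + training summary."""
        self._check_fitted()
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        config = {"class": "PeptideConvNet", "allele": allele, **self.get_params()}
        (directory / "config.json").write_text(json.dumps(config, indent=2))
        summary = {
            "examples_seen": self.n_examples_,
            "epochs_run": self.epochs_run_,
            "final_train_loss": self.final_loss_,
        }
        (directory / "training_summary.json").write_text(json.dumps(summary, indent=2))
        arrays = dict(
            zip(["w1", "b1", "w2", "b2", "wd", "bd", "wo", "bo"], self.params_.as_list())
        )
        if self.channel_mean_ is not None:
            arrays["channel_mean"] = self.channel_mean_
            arrays["channel_std"] = self.channel_std_
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "PeptideConvNet":
        directory = Path(directory)
        config = json.loads((directory / "config.json").read_text())
        config.pop("class", None)
        config.pop("allele", None)
        model = cls(**config)
        with np.load(directory / "weights.npz") as blob:
            model.params_ = _Params(
                *[blob[k] for k in ["w1", "b1", "w2", "b2", "wd", "bd", "wo", "bo"]]
            )
            model.channel_mean_ = blob["channel_mean"] if "channel_mean" in blob else None
            model.channel_std_ = blob["channel_std"] if "channel_std" in blob else None
        summary = json.loads((directory / "training_summary.json").read_text())
        model.classes_ = np.array([0, 1])
        model.n_examples_ = summary["examples_seen"]
        model.epochs_run_ = summary["epochs_run"]
        model.final_loss_ = summary["final_train_loss"]
        model.history_ = []
        return model


class LengthGroupedConvNet(BaseEstimator, ClassifierMixin):
    """Four-submodel variant routing peptides by length group.

    Peptides are grouped as L<=8, L=9, L=10, L>=11 and one
    :class:`PeptideConvNet` is trained per non-degenerate group; groups
    whose training data lacks a class fall back to the group's base rate.
    """

    GROUPS = ("L<=8", "L=9", "L=10", "L>=11")

    def __init__(self, net_params: dict | None = None):
        self.net_params = net_params

    @staticmethod
    def group_of(peptide: str) -> str:
        L = len(peptide.strip())
        if L <= 8:
            return "L<=8"
        if L == 9:
            return "L=9"
        if L == 10:
            return "L=10"
        return "L>=11"

    def fit(self, X: Sequence[str], y: Sequence[int]) -> "LengthGroupedConvNet":
        X = list(X)
        y_arr = np.asarray(y, dtype=int).ravel()
        if len(np.unique(y_arr)) < 2:
            raise DegenerateDataError("training requires both classes present")
        self.models_: dict[str, PeptideConvNet | float] = {}
        groups = np.array([self.group_of(p) for p in X])
        for g in self.GROUPS:
            mask = groups == g
            if not mask.any():
                self.models_[g] = float(y_arr.mean())  # unseen group: global base rate
                continue
            yg = y_arr[mask]
            if len(np.unique(yg)) < 2 or mask.sum() < 2:
                self.models_[g] = float(yg.mean())
            else:
                net = PeptideConvNet(**(self.net_params or {}))
                net.fit([x for x, m in zip(X, mask) if m], yg)
                self.models_[g] = net
        self.classes_ = np.array([0, 1])
        return self

    def decision_scores(self, X: Sequence[str]) -> np.ndarray:
        X = list(X)
        out = np.empty(len(X))
        groups = np.array([self.group_of(p) for p in X]) if X else np.empty(0, dtype=str)
        for g in set(groups.tolist()):
            mask = groups == g
            model = self.models_[g]
            if isinstance(model, float):
                out[mask] = model
            else:
                out[mask] = model.decision_scores([x for x, m in zip(X, mask) if m])
        return out

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        p1 = self.decision_scores(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: Sequence[str]) -> np.ndarray:
        threshold = (self.net_params or {}).get("threshold", 0.5)
        return (self.decision_scores(X) >= threshold).astype(int)
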