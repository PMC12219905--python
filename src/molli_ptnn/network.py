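"""The personalized T1 regression network.

A small densely connected network (8 -> 40 -> 20 -> 8 -> 1, ReLU hidden
layers, linear output) maps a unit-normalized 8-sample MOLLI signal to a T1
estimate in ms.  It is trained per acquisition on the simulated signal
database for that acquisition's exact ECG timing, with mean-squared-error
loss and Adam (learning rate 0.001, beta1 0.6, beta2 0.95), batch size 20,
for a fixed 100 epochs.  Training is fully deterministic for a given seed:
weight initialization, epoch shuffling and the optimizer state are all driven
by one seeded generator, and the forward/backward passes are plain numpy.

``PTNNRegressor`` follows the scikit-learn estimator contract (get_params /
set_params, ``fit`` with trailing-underscore fitted attributes, ``predict``),
so it composes with sklearn model selection; ``train_network`` /
``predict_t1`` are thin functional wrappers used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .database import SignalDatabase

__all__ = [
    "PTNNRegressor",
    "SplitSpec",
    "TrainedNetwork",
    "split_dataset",
    "train_network",
    "predict_t1",
]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/validation/test partition fractions (default 70/28/2)."""

    train: float = 0.70
    validation: float = 0.28
    test: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train + self.validation + self.test
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if min(self.train, self.validation, self.test) <= 0:
            raise ValueError("all split fractions must be positive")


def split_dataset(db: SignalDatabase, split: SplitSpec
                  ) -> tuple[SignalDatabase, SignalDatabase, SignalDatabase]:
    """Seeded disjoint partition into (train, validation, test) databases.

    Validation and test sizes are floor(fraction * N); rounding remainders go
    to the training split.
    """
    n = len(db)
    if n < 50:
        raise ValueError("database too small to split meaningfully")
    n_val = int(np.floor(split.validation * n))
    n_test = int(np.floor(split.test * n))
    perm = np.random.default_rng(split.seed).permutation(n)
    test_idx = perm[:n_test]
    val_idx = perm[n_test:n_test + n_val]
    train_idx = perm[n_test + n_val:]
    return db.subset(train_idx), db.subset(val_idx), db.subset(test_idx)


class PTNNRegressor(BaseEstimator, RegressorMixin):
    """Densely connected T1 regressor trained on simulated MOLLI signals.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Hidden widths; (40, 20, 8) by default.
    learning_rate, beta1, beta2, eps : float
        Adam hyperparameters.
    batch_size, epochs : int
        Fixed-length training: no early stopping, the validation set (if
        passed to ``fit``) is monitored only.
    standardize_inputs : bool
        Internally z-score the 8 features with training-set statistics (the
        affine transform is part of the fitted model and applied identically
        at prediction).  Unit-norm MOLLI vectors have tiny per-feature
        variance, which stalls first-layer learning without this.
    target_scale : float
        Targets are divided by this during optimization (default 1000, i.e.
        T1 in seconds-scale units); predictions and recorded losses are
        mapped back to ms and ms^2.
    check_normalized : bool
        If True (default), ``predict`` rejects inputs whose rows are not
        unit-L2 within 1e-6, catching a missing normalization step.
    random_state : int or None
        Seed for weight initialization and epoch shuffling; fixing it makes
        training bit-reproducible on a given platform.

    Attributes (after ``fit``)
    --------------------------
    coefs_, intercepts_ : per-layer weights.
    loss_curve_ : mean training MSE per epoch, ms^2 (running average over
        batches, so it trails the end-of-epoch weights).
    validation_loss_curve_ : per-epoch validation MSE, ms^2, or None.
    final_train_loss_ : training MSE of the final weights, ms^2.
    """

    def __init__(self, hidden_layer_sizes=(40, 20, 8), learning_rate=0.001,
                 beta1=0.6, beta2=0.95, eps=1e-8, batch_size=20, epochs=100,
                 standardize_inputs=True, target_scale=1000.0,
                 check_normalized=True, random_state=None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.batch_size = batch_size
        self.epochs = epochs
        self.standardize_inputs = standardize_inputs
        self.target_scale = target_scale
        self.check_normalized = check_normalized
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _init_weights(self, sizes, rng):
        # uniform fan-in initialization: U(-1/sqrt(fan_in), 1/sqrt(fan_in))
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            biases.append(rng.uniform(-bound, bound, size=fan_out))
        return weights, biases

    def _forward(self, X):
        """Return per-layer activations; last entry is the (n,) prediction."""
        acts = [X]
        a = X
        n_hidden = len(self.coefs_) - 1
        for i, (W, c) in enumerate(zip(self.coefs_, self.intercepts_)):
            z = a @ W + c
            a = np.maximum(z, 0.0) if i < n_hidden else z
            acts.append(a)
        return acts

    def _adam_step(self, grads, moments, t):
        lr, b1, b2 = self.learning_rate, self.beta1, self.beta2
        bias1 = 1.0 - b1 ** t
        bias2 = 1.0 - b2 ** t
        for p, g, m, v in moments_iter(self.coefs_ + self.intercepts_, grads,
                                       moments):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train for exactly ``epochs`` epochs on (X, y); y is T1 in ms.

        Records ``loss_curve_`` (mean training MSE per epoch) and, when a
        validation set is supplied, ``validation_loss_curve_``.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 8:
            raise ValueError(
                f"expected 8 intensities per input, got shape {X.shape}")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if self.standardize_inputs:
            self.x_offset_ = X.mean(axis=0)
            self.x_scale_ = np.maximum(X.std(axis=0), 1e-12)
        else:
            self.x_offset_ = np.zeros(X.shape[1])
            self.x_scale_ = np.ones(X.shape[1])
        X = (X - self.x_offset_) / self.x_scale_
        y = y / self.target_scale
        if X_val is not None:
            X_val = (np.asarray(X_val, float) - self.x_offset_) / self.x_scale_
            y_val = np.asarray(y_val, float).ravel() / self.target_scale
        rng = np.random.default_rng(self.random_state)
        sizes = [X.shape[1], *self.hidden_layer_sizes, 1]
        self.coefs_, self.intercepts_ = self._init_weights(sizes, rng)
        n_params = len(self.coefs_) + len(self.intercepts_)
        moments = [(np.zeros_like(p), np.zeros_like(p))
                   for p in self.coefs_ + self.intercepts_]
        self.loss_curve_ = []
        self.validation_loss_curve_ = [] if X_val is not None else None
        t = 0
        n = len(X)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                grads, batch_loss = self._batch_gradients(X[idx], y[idx])
                if not np.isfinite(batch_loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                epoch_loss += batch_loss * len(idx)
                t += 1
                self._adam_step(grads, moments, t)
            self.loss_curve_.append(epoch_loss / n * self.target_scale ** 2)
            if X_val is not None:
                pred = self._forward(X_val)[-1][:, 0]
                self.validation_loss_curve_.append(
                    float(np.mean((pred - y_val) ** 2)) * self.target_scale ** 2)
        final_pred = self._forward(X)[-1][:, 0]
        self.final_train_loss_ = float(
            np.mean((final_pred - y) ** 2)) * self.target_scale ** 2
        self.n_features_in_ = X.shape[1]
        self.n_iter_ = self.epochs
        return self

    def _batch_gradients(self, Xb, yb):
        acts = self._forward(Xb)
        pred = acts[-1][:, 0]
        resid = pred - yb
        loss = float(np.mean(resid ** 2))
        nb = len(Xb)
        # dL/dpred for MSE
        delta = (2.0 / nb) * resid[:, None]
        gw = [None] * len(self.coefs_)
        gb = [None] * len(self.intercepts_)
        for i in range(len(self.coefs_) - 1, -1, -1):
            a_prev = acts[i]
            gw[i] = a_prev.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.coefs_[i].T) * (acts[i] > 0)
        return gw + gb, loss

    def predict(self, X):
        """T1 estimates (ms), one per row; order preserved, no clipping."""
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected (n, {self.n_features_in_}) input")
        if self.check_normalized:
            norms = np.linalg.norm(X, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError(
                    "input signals are not unit-L2 normalized; apply the same "
                    "normalization used at training time")
        X = (X - self.x_offset_) / self.x_scale_
        return self._forward(X)[-1][:, 0] * self.target_scale


def moments_iter(params, grads, moments):
    for p, g, (m, v) in zip(params, grads, moments):
        yield p, g, m, v


@dataclass
class TrainedNetwork:
    """A fitted per-acquisition regressor plus its provenance."""

    model: PTNNRegressor
    schedule_fingerprint: str
    seed: int | None
    loss_curve: list = field(default_factory=list)
    validation_loss_curve: list | None = None

    def predict(self, signals: np.ndarray) -> np.ndarray:
        return self.model.predict(signals)


def train_network(train: SignalDatabase, validation: SignalDatabase | None,
                  seed: int, **spec_overrides) -> TrainedNetwork:
    """Train the personalized network on a (normalized) signal database."""
    if not train.normalized:
        raise ValueError("training database must be normalized first")
    model = PTNNRegressor(random_state=seed, **spec_overrides)
    X_val = y_val = None
    if validation is not None:
        if not validation.normalized:
            raise ValueError("validation database must be normalized first")
        X_val, y_val = validation.signals, validation.t1
    model.fit(train.signals, train.t1, X_val=X_val, y_val=y_val)
    return TrainedNetwork(
        model=model,
        schedule_fingerprint=train.schedule_fingerprint,
        seed=seed,
        loss_curve=list(model.loss_curve_),
        validation_loss_curve=(None if model.validation_loss_curve_ is None
                               else list(model.validation_loss_curve_)),
    )


def predict_t1(net: TrainedNetwork, signals: np.ndarray,
               schedule_fingerprint: str | None = None) -> np.ndarray:
    """Apply a trained network to normalized 8-vectors; warns on a timing
    fingerprint mismatch (the network is only valid for its own schedule)."""
    if schedule_fingerprint is not None and (
            schedule_fingerprint != net.schedule_fingerprint):
        import warnings

        warnings.warn(
            "schedule fingerprint mismatch: the network was trained for a "
            "different acquisition timing", stacklevel=2)
    return net.predict(np.asarray(signals, dtype=float))
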