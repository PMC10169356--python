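"""Convolutional sequence classifiers and their training protocol.

Two architectures are provided, each with a ReLU or exponential first-layer
activation (four models total).  Both take (L=200, A=4) one-hot input, apply
batch normalization before every hidden activation, and end in a single
sigmoid output:

* shallow — conv(24 filters, width 19) / maxpool 50 / conv(48, 3) /
  maxpool 2 / dense 96, dropout 0.1 and 0.2 after the two conv blocks;
* deep — conv(24, 19) / conv(32, 7) / maxpool 4 / conv(48, 7) / maxpool 4 /
  conv(64, 3) / maxpool 3 / dense 96, dropout 0.1/0.2/0.3/0.4 after the conv
  blocks and 0.5 after the dense layer.

Training minimizes binary cross-entropy with Adam (initial learning rate
1e-3, batch 100), decays the learning rate by 0.2 when validation AUC
plateaus for 3 epochs, and restores the weights from the epoch with the
highest validation AUC.  L2 (1e-6) applies to conv/dense weights but not to
batch-norm parameters.  An optional off-simplex penalty on the input
gradient can be added to the loss to steer the learned function to align
with the data simplex.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from .containers import AttributionMap
from .nn import (
    Adam,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    ExpActivation,
    Flatten,
    MaxPool1D,
    Network,
    ReLU,
    bce_with_logits,
)

_SHALLOW_DROPOUT = (0.1, 0.2)
_DEEP_DROPOUT = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class ModelSpec:
    """Architecture hyperparameters for one model variant."""

    architecture: str = "deep"  # {"shallow", "deep"}
    first_layer_activation: str = "relu"  # {"relu", "exponential"}
    first_layer_filters: int = 24
    input_length: int = 200
    l2_strength: float = 1e-6
    init_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.architecture not in ("shallow", "deep"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.first_layer_activation not in ("relu", "exponential", "exp"):
            raise ValueError(f"unknown activation {self.first_layer_activation!r}")


@dataclass
class TrainConfig:
    """Optimization settings; defaults are the desk-scale protocol."""

    epochs: int = 30
    batch_size: int = 100
    learning_rate: float = 1e-3
    lr_decay: float = 0.2
    lr_patience: int = 3
    early_stopping: int = 5  # epochs without val-AUC improvement; 0 disables
    penalty_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


def _first_activation(name: str):
    return ExpActivation() if name in ("exponential", "exp") else ReLU()


def _build_network(spec: ModelSpec, rng: np.random.Generator, dtype) -> Network:
    f1 = spec.first_layer_filters
    g = spec.init_gain
    if spec.architecture == "shallow":
        pooled = spec.input_length // 50 // 2
        layers = [
            Conv1D(4, f1, 19, rng, gain=g, dtype=dtype),
            BatchNorm(f1, dtype=dtype),
            _first_activation(spec.first_layer_activation),
            MaxPool1D(50),
            Dropout(_SHALLOW_DROPOUT[0]),
            Conv1D(f1, 48, 3, rng, gain=g, dtype=dtype),
            BatchNorm(48, dtype=dtype),
            ReLU(),
            MaxPool1D(2),
            Dropout(_SHALLOW_DROPOUT[1]),
            Flatten(),
            Dense(pooled * 48, 96, rng, gain=g, dtype=dtype),
            BatchNorm(96, dtype=dtype),
            ReLU(),
            Dense(96, 1, rng, gain=g, dtype=dtype),
        ]
    else:
        pooled = spec.input_length // 4 // 4 // 3
        layers = [
            Conv1D(4, f1, 19, rng, gain=g, dtype=dtype),
            BatchNorm(f1, dtype=dtype),
            _first_activation(spec.first_layer_activation),
            Dropout(_DEEP_DROPOUT[0]),
            Conv1D(f1, 32, 7, rng, gain=g, dtype=dtype),
            BatchNorm(32, dtype=dtype),
            ReLU(),
            MaxPool1D(4),
            Dropout(_DEEP_DROPOUT[1]),
            Conv1D(32, 48, 7, rng, gain=g, dtype=dtype),
            BatchNorm(48, dtype=dtype),
            ReLU(),
            MaxPool1D(4),
            Dropout(_DEEP_DROPOUT[2]),
            Conv1D(48, 64, 3, rng, gain=g, dtype=dtype),
            BatchNorm(64, dtype=dtype),
            ReLU(),
            MaxPool1D(3),
            Dropout(_DEEP_DROPOUT[3]),
            Flatten(),
            Dense(pooled * 64, 96, rng, gain=g, dtype=dtype),
            BatchNorm(96, dtype=dtype),
            ReLU(),
            Dropout(_DEEP_DROPOUT[4]),
            Dense(96, 1, rng, gain=g, dtype=dtype),
        ]
    return Network(layers)


class SequenceCNN(BaseEstimator, ClassifierMixin):
    """Binary sequence classifier over one-hot (L, A) inputs.

    Implements the predictor contract used by all attribution methods:
    ``predict_proba`` for scalar predictions and :meth:`input_gradient` for
    saliency queries, computed by the same reverse pass that trains the
    network (evaluation mode: running batch-norm statistics, no dropout).

    Parameters mirror :class:`ModelSpec` and :class:`TrainConfig`.  Use
    ``dtype="float64"`` when comparing gradients against finite differences.
    """

    def __init__(
        self,
        architecture: str = "deep",
        first_layer_activation: str = "relu",
        first_layer_filters: int = 24,
        input_length: int = 200,
        l2_strength: float = 1e-6,
        init_gain: float = 1.0,
        epochs: int = 30,
        batch_size: int = 100,
        learning_rate: float = 1e-3,
        lr_decay: float = 0.2,
        lr_patience: int = 3,
        early_stopping: int = 5,
        penalty_weight: float = 0.0,
        penalty_delta: float = 0.1,
        validation_fraction: float = 0.1,
        random_state: int | None = 0,
        dtype: str = "float32",
        verbose: int = 0,
    ):
        self.architecture = architecture
        self.first_layer_activation = first_layer_activation
        self.first_layer_filters = first_layer_filters
        self.input_length = input_length
        self.l2_strength = l2_strength
        self.init_gain = init_gain
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.lr_patience = lr_patience
        self.early_stopping = early_stopping
        self.penalty_weight = penalty_weight
        self.penalty_delta = penalty_delta
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.dtype = dtype
        self.verbose = verbose

    # -- construction -------------------------------------------------

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            architecture=self.architecture,
            first_layer_activation=self.first_layer_activation,
            first_layer_filters=self.first_layer_filters,
            input_length=self.input_length,
            l2_strength=self.l2_strength,
            init_gain=self.init_gain,
        )

    @property
    def _np_dtype(self):
        return np.float64 if str(self.dtype) == "float64" else np.float32

    def initialize(self) -> "SequenceCNN":
        """Build and seed the network without training (weights reproducible from seed)."""
        self._spec()  # validates names
        init_rng = np.random.default_rng(np.random.SeedSequence(self.random_state))
        self.network_ = _build_network(self._spec(), init_rng, self._np_dtype)
        self.classes_ = np.array([0, 1])
        return self

    # -- core passes ---------------------------------------------------

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=self._np_dtype)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != self.input_length or X.shape[2] != 4:
            raise ValueError(
                f"expected input of shape (N, {self.input_length}, 4), got {X.shape}"
            )
        self._single = single
        return X

    def decision_function(self, X) -> np.ndarray:
        """Pre-sigmoid logit per sequence."""
        X = self._check_X(X)
        out = np.concatenate(
            [
                self.network_.forward(X[i : i + 256], training=False).reshape(-1)
                for i in range(0, len(X), 256)
            ]
        )
        return out[0] if self._single else out

    def predict_proba(self, X) -> np.ndarray:
        z = np.atleast_1d(self.decision_function(X)).astype(np.float64)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_score(self, X) -> np.ndarray:
        """Sigmoid output in (0, 1) per sequence (scalar for a single sequence)."""
        p = self.predict_proba(np.asarray(X))[:, 1]
        return float(p[0]) if getattr(self, "_single", False) else p

    def input_gradient(self, X, output: str = "logit") -> np.ndarray:
        """Gradient of the chosen output w.r.t. the one-hot input.

        ``output="logit"`` (default) differentiates the pre-sigmoid score;
        ``output="prob"`` differentiates the sigmoid output.  Evaluation
        mode throughout.  Returns (N, L, A) float64 (or (L, A) for a single
        sequence).
        """
        X = self._check_X(X)
        single = self._single
        grads = []
        for i in range(0, len(X), 256):
            xb = X[i : i + 256]
            z = self.network_.forward(xb, training=False)
            if output == "logit":
                dz = np.ones_like(z)
            elif output == "prob":
                p = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
                dz = (p * (1 - p)).astype(z.dtype)
            else:
                raise ValueError("output must be 'logit' or 'prob'")
            grads.append(self.network_.backward(dz).astype(np.float64))
        g = np.concatenate(grads)
        return g[0] if single else g

    def attribution_maps(self, X, ids=None, output: str = "logit") -> list[AttributionMap]:
        g = np.atleast_3d(self.input_gradient(X, output=output))
        ids = ids or [f"seq{i:06d}" for i in range(len(g))]
        return [AttributionMap(scores=g[i], sequence_id=str(ids[i])) for i in range(len(g))]

    # -- training ------------------------------------------------------

    def _penalty_gradient(self, xb: np.ndarray, rng: np.random.Generator) -> dict:
        """Parameter gradient of a stochastic surrogate for the off-simplex penalty.

        The target is P = mean_{n,l} ||G_perp||^2, the mean squared component
        of the input gradient along the per-position simplex normal
        n = (1/sqrt(A))(1,..,1).  With random signs r_{n,l} and the
        perturbation R_{n,l,a} = r_{n,l}/sqrt(A), the squared symmetric
        difference quotient

            q = (F(x + dR) - F(x - dR)) / (2d),   F = batch-summed logit,

        satisfies E_r[q^2]/(N L) -> P as d -> 0.  We descend q^2/(N L)
        directly: its theta-gradient is exact (two extra forward/backward
        passes, evaluation mode so the penalized function is the one
        attribution sees), unlike a finite difference *of gradients*, which
        picks up spurious kink-crossing terms in ReLU/max-pool networks.
        """
        n, length, a = xb.shape
        d = self.penalty_delta
        r = rng.choice(np.array([-1.0, 1.0], dtype=xb.dtype), size=(n, length, 1))
        R = np.broadcast_to(r / np.sqrt(a), xb.shape).astype(xb.dtype)

        zp = self.network_.forward(xb + d * R, training=False)
        fp = float(zp.sum())
        zm = self.network_.forward(xb - d * R, training=False)
        fm = float(zm.sum())
        q = (fp - fm) / (2 * d)
        # d(q^2/(NL))/dtheta = 2q/(NL) * [grad_theta F(x+dR) - grad_theta F(x-dR)] / (2d)
        scale = 2.0 * q / (n * length * 2 * d)
        self.network_.backward(np.full_like(zm, -scale))  # caches hold the x - dR pass
        grads_m = {k: g.copy() for k, g in self.network_.gradients()}
        self.network_.forward(xb + d * R, training=False)
        self.network_.backward(np.full_like(zp, scale))
        return {k: g + grads_m[k] for k, g in self.network_.gradients()}

    def fit(self, X, y, X_val=None, y_val=None):
        """Train with mini-batch Adam, restoring the best-validation-AUC weights.

        If no validation set is given, ``validation_fraction`` of the data is
        held out (stratified by the shuffle of a balanced input).
        """
        X = np.asarray(X, dtype=self._np_dtype)
        y = np.asarray(y).reshape(-1)
        if X.ndim != 3 or len(X) != len(y):
            raise ValueError("X must be (N, L, A) with matching labels")
        ss = np.random.SeedSequence(self.random_state)
        init_ss, shuffle_ss, drop_ss, split_ss, pen_ss = ss.spawn(5)
        self.network_ = _build_network(self._spec(), np.random.default_rng(init_ss), self._np_dtype)
        self.classes_ = np.unique(y) if len(np.unique(y)) == 2 else np.array([0, 1])

        if X_val is None:
            idx = np.random.default_rng(split_ss).permutation(len(X))
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            X_val = np.asarray(X_val, dtype=self._np_dtype)
            y_val = np.asarray(y_val).reshape(-1)

        opt = Adam(lr=self.learning_rate)
        shuffle_rng = np.random.default_rng(shuffle_ss)
        drop_rng = np.random.default_rng(drop_ss)
        pen_rng = np.random.default_rng(pen_ss)
        history = {"loss": [], "val_auc": [], "lr": []}
        best_auc, best_weights = -np.inf, None
        lr_wait = 0
        es_wait = 0

        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), self.batch_size):
                batch = order[start : start + self.batch_size]
                xb, yb = X[batch], y[batch]
                # the penalty pass runs its own forward/backward sweeps, so it
                # must come before the loss pass whose caches/grads we keep
                pen = (
                    self._penalty_gradient(xb, pen_rng) if self.penalty_weight > 0 else None
                )
                z = self.network_.forward(xb, training=True, rng=drop_rng)
                loss, dz = bce_with_logits(z, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}, "
                        f"batch {start // self.batch_size}"
                    )
                self.network_.backward(dz.astype(z.dtype))
                self.network_.add_l2_gradient(self.l2_strength)
                if pen is not None:
                    for layer_i, layer in enumerate(self.network_.layers):
                        for name in layer.params:
                            layer.grads[name] = (
                                layer.grads[name] + self.penalty_weight * pen[(layer_i, name)]
                            )
                opt.step(self.network_)
                losses.append(loss)

            val_scores = self.predict_proba(X_val)[:, 1]
            if not np.all(np.isfinite(val_scores)):
                raise RuntimeError(
                    f"training diverged (non-finite predictions) at epoch {epoch}"
                )
            val_auc = roc_auc_score(y_val, val_scores)
            history["loss"].append(float(np.mean(losses)))
            history["val_auc"].append(float(val_auc))
            history["lr"].append(float(opt.lr))
            if self.verbose:
                print(
                    f"epoch {epoch + 1:3d}  loss {history['loss'][-1]:.4f}  "
                    f"val_auc {val_auc:.4f}  lr {opt.lr:.2e}"
                )

            if val_auc > best_auc:
                best_auc = float(val_auc)
                best_weights = self.network_.get_weights()
                lr_wait = 0
                es_wait = 0
            else:
                lr_wait += 1
                es_wait += 1
                if lr_wait > self.lr_patience:
                    opt.lr *= self.lr_decay
                    lr_wait = 0
                if self.early_stopping and es_wait >= self.early_stopping:
                    break

        if best_weights is not None:
            self.network_.set_weights(best_weights)
        self.history_ = history
        self.best_val_auc_ = best_auc
        return self

    def summary(self) -> list[tuple[str, tuple, int]]:
        return self.network_.summary((self.input_length, 4))


# -- module-level operations (thin wrappers over the estimator) --------


def build_model(spec: ModelSpec, seed: int = 0, dtype: str = "float32") -> SequenceCNN:
    """Construct and initialize a model from an architecture spec."""
    return SequenceCNN(
        architecture=spec.architecture,
        first_layer_activation=spec.first_layer_activation,
        first_layer_filters=spec.first_layer_filters,
        input_length=spec.input_length,
        l2_strength=spec.l2_strength,
        init_gain=spec.init_gain,
        random_state=seed,
        dtype=dtype,
    ).initialize()


def train(model: SequenceCNN, splits, config: TrainConfig) -> SequenceCNN:
    """Train a model on dataset splits under the given protocol."""
    for attr, value in asdict(config).items():
        if attr == "seed":
            model.random_state = value
        else:
            setattr(model, attr, value)
    X_tr, y_tr, _ = splits.arrays("train")
    X_va, y_va, _ = splits.arrays("valid")
    return model.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)


def save_model(model: SequenceCNN, path) -> None:
    """Write weights (.npz) plus a sidecar JSON with the constructor parameters."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {}
    for i, layer in enumerate(model.network_.layers):
        for name, value in layer.params.items():
            arrays[f"layer{i}.{name}"] = value
        for name, value in layer.state.items():
            arrays[f"layer{i}.state.{name}"] = value
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    meta = {"params": model.get_params(), "best_val_auc": getattr(model, "best_val_auc_", None)}
    sidecar.write_text(json.dumps(meta, indent=2, default=float))


def load_model(path) -> SequenceCNN:
    """Restore a model written by :func:`save_model`."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = SequenceCNN(**meta["params"]).initialize()
    with np.load(path) as z:
        for i, layer in enumerate(model.network_.layers):
            for name in layer.params:
                layer.params[name] = z[f"layer{i}.{name}"]
            for name in list(layer.state):
                key = f"layer{i}.state.{name}"
                if key in z:
                    setattr(layer, name, z[key])
    if meta.get("best_val_auc") is not None:
        model.best_val_auc_ = meta["best_val_auc"]
    return model


def train_ensemble(
    base_spec: ModelSpec,
    splits,
    config: TrainConfig,
    filter_counts: list[int] | None = None,
    per_count: int = 1,
) -> list[SequenceCNN]:
    """Train one model per (first-layer filter count, replicate) with distinct seeds.

    The full-scale proxy-ground-truth ensemble uses ten filter counts
    (12..30 step 2) with five replicates each; smaller configurations serve
    as scaled-down stand-ins.
    """
    if per_count < 1:
        raise ValueError("per_count must be >= 1")
    filter_counts = filter_counts or [12, 14, 16, 18, 20, 22, 24, 26, 28, 30]
    seeds = np.random.SeedSequence(config.seed).generate_state(len(filter_counts) * per_count)
    models = []
    i = 0
    for fc in filter_counts:
        for _ in range(per_count):
            spec = ModelSpec(**{**asdict(base_spec), "first_layer_filters": int(fc)})
            model = build_model(spec, seed=int(seeds[i] % (2**31)))
            cfg = TrainConfig(**{**asdict(config), "seed": int(seeds[i] % (2**31))})
            models.append(train(model, splits, cfg))
            i += 1
    return models
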