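"""Multilayer-perceptron emotion-intensity regressor, written from scratch.

The network maps a feature vector to five emotion intensities. Forward pass:
induced local field v_j = Σ w_ji·x_i + b_j, hidden activation sigmoid
(1/(1+e^{-a·v}), slope a ≥ 1) or ReLU, output activation sigmoid in
regression mode (intensities in (0,1)) or softmax in classification mode.
Training minimizes the mean instantaneous error energy ξ = ½Σ_j ε_j² with
ε_j = d_j − y_j. The output-layer local gradient is δ_k = ε_k·φ'(v_k)
(for sigmoid, ε_k·a·y_k(1−y_k)); hidden deltas follow the standard
backpropagation chain. Updates use the delta rule with momentum,
Δw_kj(n) = α·Δw_kj(n−1) + η·δ_k·y_j (y_j the presynaptic activation), or
Adam on the same gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix


@dataclass
class NetworkSpec:
    n_input: int
    hidden: tuple[int, ...] = (10, 10)
    n_output: int = 5
    activation: str = "sigmoid"  # hidden-layer activation: sigmoid | relu
    sigmoid_slope: float = 1.0  # a >= 1
    output_mode: str = "regression"  # regression (sigmoid) | classification (softmax)
    optimizer: str = "sgd"  # delta rule with momentum | adam
    learning_rate: float = 0.5  # η in [0, 1]
    momentum: float = 0.9  # α in [0, 1]
    epochs: int = 6000
    batch_mode: str = "batch"  # batch (vectorized) | online (per-sample)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_input < 1 or self.n_output < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("layer widths must be positive")
        if self.activation not in ("sigmoid", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.output_mode not in ("regression", "classification"):
            raise ValueError(f"unknown output mode {self.output_mode!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if not 0 <= self.learning_rate <= 1:
            raise ValueError("learning rate must lie in [0, 1]")
        if not 0 <= self.momentum <= 1:
            raise ValueError("momentum must lie in [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.sigmoid_slope < 1:
            raise ValueError("sigmoid slope a must be >= 1")

    @property
    def layer_widths(self) -> list[tuple[int, int]]:
        dims = [self.n_input, *self.hidden, self.n_output]
        return [(dims[i + 1], dims[i]) for i in range(len(dims) - 1)]


@dataclass
class MLPModel:
    spec: NetworkSpec
    weights: list[np.ndarray]  # per layer, (n_out, n_in)
    biases: list[np.ndarray]  # per layer, (n_out,)
    loss_trace: list[float] = field(default_factory=list)  # mean ξ per epoch
    feature_names: list[str] | None = None

    @property
    def n_layers(self) -> int:
        return len(self.weights)


def init_network(spec: NetworkSpec) -> MLPModel:
    """Glorot-style scaled-uniform weights, zero biases; seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    weights, biases = [], []
    for n_out, n_in in spec.layer_widths:
        limit = np.sqrt(6.0 / (n_in + n_out))
        weights.append(rng.uniform(-limit, limit, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    return MLPModel(spec=spec, weights=weights, biases=biases)


def _sigmoid(v: np.ndarray, a: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-a * np.clip(v, -500 / a, 500 / a)))


def _softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _forward_full(
    model: MLPModel, X: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """All layer pre-activations and activations for a (n, d) batch."""
    spec = model.spec
    ys = [X]
    vs = []
    for layer, (W, b) in enumerate(zip(model.weights, model.biases)):
        v = ys[-1] @ W.T + b
        vs.append(v)
        is_output = layer == model.n_layers - 1
        if is_output:
            if spec.output_mode == "regression":
                y = _sigmoid(v, spec.sigmoid_slope)
            else:
                y = _softmax(v)
        elif spec.activation == "sigmoid":
            y = _sigmoid(v, spec.sigmoid_slope)
        else:
            y = np.maximum(v, 0.0)
        ys.append(y)
    return vs, ys


def forward(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Network output for one feature vector or an (n, d) batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.spec.n_input:
        raise ValueError(
            f"input width {X.shape[1]} != network input width {model.spec.n_input}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite network input")
    _, ys = _forward_full(model, X)
    out = ys[-1]
    return out[0] if single else out


def mean_error_energy(model: MLPModel, X: np.ndarray, D: np.ndarray) -> float:
    """Mean over samples of the per-sample energy Σ_j ½ε_j²."""
    Y = forward(model, X)
    return float(np.mean(np.sum(0.5 * (D - Y) ** 2, axis=-1)))


def _hidden_derivative(spec: NetworkSpec, v: np.ndarray, y: np.ndarray) -> np.ndarray:
    if spec.activation == "sigmoid":
        return spec.sigmoid_slope * y * (1.0 - y)
    return (v > 0).astype(float)  # ReLU subgradient; 0 at v == 0


def gradients(
    model: MLPModel, X: np.ndarray, D: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """∂(mean energy)/∂W and ∂/∂b for every layer, by backpropagation."""
    spec = model.spec
    n = X.shape[0]
    vs, ys = _forward_full(model, X)
    Y = ys[-1]
    err = D - Y  # ε
    if spec.output_mode == "regression":
        delta = err * spec.sigmoid_slope * Y * (1.0 - Y)  # Eq-style δ_k
    else:
        # softmax Jacobian applied to dL/dy = -ε (loss is squared error)
        g = err
        delta = Y * (g - np.sum(g * Y, axis=-1, keepdims=True))
    gw, gb = [None] * model.n_layers, [None] * model.n_layers
    for layer in range(model.n_layers - 1, -1, -1):
        # gradient of the *loss* is the negative of the delta-rule direction
        gw[layer] = -(delta.T @ ys[layer]) / n
        gb[layer] = -delta.mean(axis=0)
        if layer > 0:
            back = delta @ model.weights[layer]
            delta = back * _hidden_derivative(spec, vs[layer - 1], ys[layer])
    return gw, gb


class _Adam:
    def __init__(self, shapes, beta1=0.9, beta2=0.999, eps=1e-8):
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, grads, lr):
        self.t += 1
        out = []
        for i, g in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            out.append(-lr * mh / (np.sqrt(vh) + self.eps))
        return out


def train(
    model: MLPModel,
    X: np.ndarray | FeatureMatrix,
    D: np.ndarray | None = None,
    epochs: int | None = None,
) -> MLPModel:
    """Train in place for ``epochs`` passes; returns the model.

    Accepts either a :class:`FeatureMatrix` (targets taken from it, column
    names recorded for the prediction manifest) or raw arrays. Data order is
    fixed — training is reproducible given (seed, data).
    """
    if isinstance(X, FeatureMatrix):
        model.feature_names = list(X.feature_names)
        D = X.y.to_numpy()
        X = X.X.to_numpy()
    X = np.asarray(X, dtype=float)
    D = np.asarray(D, dtype=float)
    if X.size == 0:
        raise ValueError("empty training set")
    if D.min() < 0 or D.max() > 1:
        raise ValueError("targets must lie in [0, 1]")
    spec = model.spec
    n_epochs = epochs if epochs is not None else spec.epochs

    params = model.weights + model.biases

    def _apply(updates):
        for p, u in zip(params, updates):
            p += u

    shapes = [p.shape for p in params]
    adam = _Adam(shapes) if spec.optimizer == "adam" else None
    prev = [np.zeros(s) for s in shapes]  # momentum memory Δw(n−1)

    def _step(Xb, Db):
        gw, gb = gradients(model, Xb, Db)
        grads = gw + gb
        if adam is not None:
            updates = adam.step(grads, spec.learning_rate)
        else:
            updates = [
                spec.momentum * pv - spec.learning_rate * g
                for pv, g in zip(prev, grads)
            ]
            prev[:] = updates
        _apply(updates)

    for epoch in range(n_epochs):
        if spec.batch_mode == "online":
            for i in range(X.shape[0]):
                _step(X[i : i + 1], D[i : i + 1])
        else:
            _step(X, D)
        loss = mean_error_energy(model, X, D)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged (NaN loss) at epoch {epoch}")
        model.loss_trace.append(loss)
    return model


def predict(model: MLPModel, X: np.ndarray | FeatureMatrix) -> np.ndarray:
    """Row-wise forward pass; (n, 5) intensities."""
    if isinstance(X, FeatureMatrix):
        if model.feature_names is not None and list(X.feature_names) != list(
            model.feature_names
        ):
            raise ValueError(
                "feature columns do not match the training manifest"
            )
        X = X.X.to_numpy()
    return forward(model, np.asarray(X, dtype=float))


def save_model(model: MLPModel, path) -> None:
    """Portable JSON checkpoint (spec + weights as nested lists)."""
    payload = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(model.spec).items()
        },
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "feature_names": model.feature_names,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> MLPModel:
    with open(path) as fh:
        payload = json.load(fh)
    sp = payload["spec"]
    sp["hidden"] = tuple(sp["hidden"])
    spec = NetworkSpec(**sp)
    return MLPModel(
        spec=spec,
        weights=[np.asarray(w) for w in payload["weights"]],
        biases=[np.asarray(b) for b in payload["biases"]],
        feature_names=payload.get("feature_names"),
    )
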