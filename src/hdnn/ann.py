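"""The dense feed-forward network embedded in every tree node.

The network is a plain multilayer perceptron, implemented directly in numpy:

* forward pass — per layer, pre-activation ``I_m = sum_k O_k w_km + w_0m``
  (weights plus bias), ReLU on hidden layers, identity on the 2-unit output;
* decision rule — the output layer is a matrix-vector inner product and the
  class is ``argmax`` of the resulting scores (ties break to the lower
  index, i.e. the negative class);
* training — mini-batch gradient descent on softmax cross-entropy, so the
  output-layer error signal is exactly ``softmax(z) - onehot(y)``; the
  gradient on a weight entry is ``(1/m) * accumulated + lambda * w`` and on
  a bias entry ``(1/m) * accumulated`` (biases are not regularized).

Dropout is inverted (activations scaled by ``1/(1-rate)`` at train time) so
inference needs no rescaling and is fully deterministic. The default
topology is ``[input, 512, 256, 64, 32, 16, 2]`` with dropout after the
256- and 16-unit layers; two epochs are the default training budget —
longer schedules overfit the tiny positive class at high imbalance ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import FeatureTable
from .errors import DomainError, NumericError, ShapeError

__all__ = [
    "NetworkSpec",
    "NetworkParams",
    "ForwardTrace",
    "TrainConfig",
    "default_spec",
    "init_params",
    "forward",
    "decision_rule",
    "batch_loss",
    "backprop_update",
    "train_ann",
]

DEFAULT_HIDDEN = (512, 256, 64, 32, 16)


@dataclass(frozen=True)
class NetworkSpec:
    """Topology and regularization layout of one node's network.

    ``layer_sizes`` includes the input and the 2-unit output.
    ``dropout_after`` holds indices into ``layer_sizes`` whose (hidden)
    outputs are dropped out at train time.
    """

    layer_sizes: tuple[int, ...]
    dropout_after: tuple[int, ...] = ()
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise DomainError("a network needs at least input and output layers")
        if self.layer_sizes[-1] != 2:
            raise DomainError("output layer must have exactly 2 units")
        if any(s < 1 for s in self.layer_sizes):
            raise DomainError("layer sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise DomainError("dropout_rate must lie in [0, 1)")
        n_layers = len(self.layer_sizes)
        for i in self.dropout_after:
            if not 1 <= i <= n_layers - 2:
                raise DomainError(
                    f"dropout index {i} must refer to a hidden layer (1..{n_layers - 2})"
                )

    @property
    def n_weight_layers(self) -> int:
        return len(self.layer_sizes) - 1


def default_spec(input_dim: int, dropout_rate: float = 0.2) -> NetworkSpec:
    """The reference topology: 512-256-64-32-16 hidden units, ReLU, dropout
    after the 256- and 16-unit layers, 2 output units."""
    sizes = (input_dim, *DEFAULT_HIDDEN, 2)
    return NetworkSpec(layer_sizes=sizes, dropout_after=(2, 5), dropout_rate=dropout_rate)


@dataclass
class NetworkParams:
    """Per-layer weight matrices (shape out x in) and bias vectors."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )

    def check_finite(self) -> None:
        for ell, (w, b) in enumerate(zip(self.weights, self.biases)):
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise NumericError(f"non-finite parameters in layer {ell}")


@dataclass
class ForwardTrace:
    """Everything the backward pass (and the router) needs from a forward pass."""

    activations: list[np.ndarray]  # layer outputs O, activations[0] = input
    pre_activations: list[np.ndarray]  # propagated inputs I per weight layer
    dropout_masks: list[np.ndarray | None]  # per weight layer, None if unused
    scores: np.ndarray  # final-layer scores y (identity output)


@dataclass(frozen=True)
class TrainConfig:
    """Mini-batch gradient-descent budget for one node's network."""

    epochs: int = 2
    batch_size: int = 32
    learning_rate: float = 0.01
    lam: float = 0.0  # L2 weight on weight entries only; biases unregularized
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise DomainError("epochs must be >= 1")
        if self.batch_size < 1:
            raise DomainError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise DomainError("learning_rate must be > 0")
        if self.lam < 0:
            raise DomainError("lambda must be >= 0")


def init_params(spec: NetworkSpec, seed: int = 0) -> NetworkParams:
    """Zero-mean Gaussian weights scaled by 1/sqrt(fan-in); zero biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(spec.layer_sizes[:-1], spec.layer_sizes[1:]):
        weights.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return NetworkParams(weights=weights, biases=biases)


def _check_input(spec: NetworkSpec, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != spec.layer_sizes[0]:
        raise ShapeError(
            f"input shape {x.shape} incompatible with input size {spec.layer_sizes[0]}"
        )
    if not np.isfinite(x).all():
        raise DomainError("non-finite input to forward pass")
    return x


def forward(
    params: NetworkParams,
    spec: NetworkSpec,
    x: np.ndarray,
    mode: str = "infer",
    seed: int | None = None,
) -> ForwardTrace:
    """Run the network on a batch (or single vector) of inputs.

    In ``train`` mode inverted dropout is applied after the configured
    hidden layers (seeded, hence reproducible); ``infer`` mode is a pure
    deterministic function of the input. The output layer is the identity:
    ``scores`` are the raw inner products fed to :func:`decision_rule`.
    """
    if mode not in ("train", "infer"):
        raise DomainError(f"mode must be 'train' or 'infer', got {mode!r}")
    X = _check_input(spec, x)
    if len(params.weights) != spec.n_weight_layers:
        raise ShapeError("parameter layer count does not match spec")

    rng = np.random.default_rng(seed) if mode == "train" else None
    rate = spec.dropout_rate
    activations = [X]
    pre_activations: list[np.ndarray] = []
    masks: list[np.ndarray | None] = []
    out = X
    n_layers = spec.n_weight_layers
    for ell, (W, b) in enumerate(zip(params.weights, params.biases)):
        if W.shape != (spec.layer_sizes[ell + 1], spec.layer_sizes[ell]):
            raise ShapeError(f"weight matrix {ell} has shape {W.shape}")
        pre = out @ W.T + b
        pre_activations.append(pre)
        if ell < n_layers - 1:
            out = np.maximum(pre, 0.0)  # ReLU on hidden layers
            layer_index = ell + 1
            if mode == "train" and rate > 0.0 and layer_index in spec.dropout_after:
                mask = (rng.random(out.shape) >= rate) / (1.0 - rate)
                out = out * mask
                masks.append(mask)
            else:
                masks.append(None)
        else:
            out = pre  # identity output layer
            masks.append(None)
        activations.append(out)
    return ForwardTrace(
        activations=activations,
        pre_activations=pre_activations,
        dropout_masks=masks,
        scores=out,
    )


def decision_rule(final_scores: np.ndarray) -> np.ndarray | int:
    """Class = argmax of the output scores; ties break to the lowest index.

    Accepts one score vector or a batch; softmax before the argmax would not
    change the result, so raw scores are used.
    """
    y = np.asarray(final_scores, dtype=np.float64)
    if y.size == 0:
        raise DomainError("empty score vector")
    if y.ndim == 1:
        if y.shape[0] < 2:
            raise DomainError("need at least 2 class scores")
        if not np.isfinite(y).all():
            raise DomainError("non-finite scores")
        return int(np.argmax(y))
    if not np.isfinite(y).all():
        raise DomainError("non-finite scores")
    return np.argmax(y, axis=1)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    y = np.zeros((labels.shape[0], 2))
    y[np.arange(labels.shape[0]), labels] = 1.0
    return y


def batch_loss(
    params: NetworkParams,
    spec: NetworkSpec,
    X: np.ndarray,
    labels: np.ndarray,
    lam: float = 0.0,
) -> float:
    """Mean softmax cross-entropy plus (lam/2) * sum of squared weights.

    This is the objective whose exact gradient the backward pass computes;
    the finite-difference tests differentiate this function.
    """
    trace = forward(params, spec, X, mode="infer")
    p = _softmax(trace.scores)
    n = X.shape[0]
    ce = -np.log(p[np.arange(n), labels] + 1e-300).mean()
    reg = 0.5 * lam * sum(float((w**2).sum()) for w in params.weights)
    return float(ce + reg)


def gradients(
    params: NetworkParams,
    spec: NetworkSpec,
    X: np.ndarray,
    labels: np.ndarray,
    lam: float = 0.0,
    dropout_seed: int | None = None,
    train_mode: bool = True,
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Backward pass: accumulate per-example error signals and form gradients.

    The output-layer error is ``softmax(z) - onehot(y)``; it is propagated
    backward through the ReLU layers (and the dropout masks actually used in
    the forward pass). Weight gradients get the additional ``lam * w`` term;
    bias gradients do not. Returns (weight grads, bias grads, batch loss).
    """
    X = _check_input(spec, X)
    labels = np.asarray(labels)
    m = X.shape[0]
    if m == 0:
        raise DomainError("empty batch")
    mode = "train" if train_mode else "infer"
    trace = forward(params, spec, X, mode=mode, seed=dropout_seed)

    probs = _softmax(trace.scores)
    n = X.shape[0]
    loss = float(
        -np.log(probs[np.arange(n), labels] + 1e-300).mean()
        + 0.5 * lam * sum(float((w**2).sum()) for w in params.weights)
    )

    delta = probs - _one_hot(labels)  # exact softmax-CE output delta
    grads_w: list[np.ndarray] = [np.empty(0)] * spec.n_weight_layers
    grads_b: list[np.ndarray] = [np.empty(0)] * spec.n_weight_layers
    for ell in range(spec.n_weight_layers - 1, -1, -1):
        a_prev = trace.activations[ell]
        grads_w[ell] = (delta.T @ a_prev) / m + lam * params.weights[ell]
        grads_b[ell] = delta.sum(axis=0) / m
        if ell > 0:
            delta = delta @ params.weights[ell]
            mask = trace.dropout_masks[ell - 1]
            if mask is not None:
                delta = delta * mask
            delta = delta * (trace.pre_activations[ell - 1] > 0.0)
    for ell, (gw, gb) in enumerate(zip(grads_w, grads_b)):
        if not (np.isfinite(gw).all() and np.isfinite(gb).all()):
            raise NumericError(f"NaN/Inf gradient in layer {ell}")
    return grads_w, grads_b, loss


def backprop_update(
    params: NetworkParams,
    spec: NetworkSpec,
    batch: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    dropout_seed: int | None = None,
) -> NetworkParams:
    """One gradient-descent step on a batch; returns new parameters."""
    X, labels = batch
    grads_w, grads_b, _ = gradients(
        params, spec, X, labels, lam=config.lam, dropout_seed=dropout_seed
    )
    new = params.copy()
    for ell in range(spec.n_weight_layers):
        new.weights[ell] -= config.learning_rate * grads_w[ell]
        new.biases[ell] -= config.learning_rate * grads_b[ell]
    return new


def train_ann(
    table: FeatureTable,
    spec: NetworkSpec,
    config: TrainConfig,
    init_seed: int | None = None,
) -> tuple[NetworkParams, list[float]]:
    """Train a fresh network on a table; returns (params, per-epoch losses).

    Runs ``config.epochs`` passes of batched gradient descent over a seeded
    shuffle of the data. Deterministic for a fixed config.
    """
    if table.n_positive == 0 or table.n_negative == 0:
        raise DomainError("training requires both classes present")
    if spec.layer_sizes[0] != table.n_features:
        raise ShapeError(
            f"spec input size {spec.layer_sizes[0]} != {table.n_features} features"
        )
    rng = np.random.default_rng(config.seed)
    params = init_params(spec, seed=init_seed if init_seed is not None else config.seed)
    X, y = table.features, table.labels
    n = table.n_samples
    losses: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            dropout_seed = int(rng.integers(0, 2**31 - 1))
            grads_w, grads_b, loss = gradients(
                params, spec, X[idx], y[idx], lam=config.lam, dropout_seed=dropout_seed
            )
            for ell in range(spec.n_weight_layers):
                params.weights[ell] -= config.learning_rate * grads_w[ell]
                params.biases[ell] -= config.learning_rate * grads_b[ell]
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise NumericError("training diverged: non-finite epoch loss")
        losses.append(epoch_loss)
    params.check_finite()
    return params, losses


def predict_ann(
    params: NetworkParams, spec: NetworkSpec, X: np.ndarray
) -> np.ndarray:
    """Convenience: infer-mode forward pass plus the argmax decision rule."""
    trace = forward(params, spec, X, mode="infer")
    return np.asarray(decision_rule(trace.scores))
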