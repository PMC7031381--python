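"""Two-convolution-layer binding classifier over peptide x HLA interaction maps.

Pure-numpy implementation: forward pass, analytic backpropagation of the
regularized negative-log-likelihood objective, mini-batch stochastic gradient
descent with momentum and a per-neuron max-norm constraint, hyperparameter
grid search, and rank-based AUC / F1 evaluation.

Architecture (no pooling, no biases, stride 1):

    input (P, 183) -> conv1 (K1 kernels, window M x 183) -> ReLU
                   -> conv2 (K2 kernels, window M2 x K1) -> ReLU
                   -> fully connected (n_hidden) -> ReLU
                   -> sigmoid output (scalar binding probability)

The objective is  NLL + l2_weight * ||W||_2^2 + l1_activation * ||H||_1,
where H is the output of the fully connected layer, plus the hard constraint
that every neuron's weight-vector L2 norm stays <= max_norm (enforced by
projection after every update).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from itertools import product
from typing import Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

from .errors import ConfigError, DegenerateLabels, ShapeError

logger = logging.getLogger(__name__)

BINDING_THRESHOLD_NM = 500.0
EPS = 1e-12

#: fraction of the HLA axis covered by the convolution kernels
HLA_WINDOW_FRACTIONS = {"half": 0.5, "two_thirds": 2.0 / 3.0, "full": 1.0}


def label_from_affinity(affinity_nm: float) -> int:
    """1 (binder) iff IC50/EC50 < 500 nM, else 0."""
    if affinity_nm <= 0:
        raise ValueError(f"affinity must be positive, got {affinity_nm}")
    return 1 if affinity_nm < BINDING_THRESHOLD_NM else 0


@dataclass
class ModelConfig:
    n_kernels1: int = 50
    n_kernels2: int = 10
    kernel_window: int = 5  # M: peptide-axis window, grid 1-5
    stride: int = 1  # fixed
    hla_window: str = "full"  # "half" | "two_thirds" | "full"
    n_hidden: int = 32
    batch_size: int = 1000
    learning_rate: float = 0.01
    momentum: float = 0.9
    l2_weight: float = 0.0001  # lambda_1
    l1_activation: float = 0.0001  # lambda_2
    max_norm: float = 3.0  # lambda_3
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride != 1:
            raise ConfigError("stride is fixed at 1")
        if self.max_norm <= 0:
            raise ConfigError("max_norm must be positive")
        if self.hla_window not in HLA_WINDOW_FRACTIONS:
            raise ConfigError(f"unknown hla_window {self.hla_window!r}")


@dataclass
class TrainingSet:
    """Stacked interaction maps with binary labels for one (locus, length) key."""

    X: np.ndarray  # (n, P, N)
    y: np.ndarray  # (n,) in {0, 1}
    key: tuple[str, int] = ("A", 9)

    def __post_init__(self) -> None:
        if self.X.ndim != 3 or len(self.X) != len(self.y):
            raise ShapeError("X must be (n, P, N) aligned with y")
        self.y = np.asarray(self.y, dtype=float)


@dataclass
class BindingModel:
    config: ModelConfig
    key: tuple[str, int]
    #: W1 (K1,M,N), W2 (K2,M2,K1), W3 (nh,F), w4 (nh,) plus per-layer biases
    #: b1 (K1,), b2 (K2,), b3 (nh,), b4 () — biases are outside the L2 penalty
    #: and the max-norm constraint, which act on weight-matrix entries only.
    weights: dict[str, np.ndarray]


@dataclass
class ForwardTrace:
    conv1: np.ndarray  # (n, P1, K1) post-ReLU
    conv2: np.ndarray  # (n, P2, K2) post-ReLU
    hidden: np.ndarray  # (n, n_hidden) post-ReLU; the H of the L1 penalty
    probability: np.ndarray  # (n,) in (0, 1)


@dataclass
class EvalReport:
    auc: float
    f1: float
    threshold: float
    n_pos: int
    n_neg: int


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def conv_forward(X: np.ndarray, kernels: np.ndarray, stride: int = 1,
                 bias: np.ndarray | None = None) -> np.ndarray:
    """ReLU convolution along the first axis; kernels span the full second axis.

    X: (n, P, N) or (P, N); kernels: (K, M, N); bias: optional (K,).
    Output: (n, P - M + 1, K) of ReLU(sum_{m,n} W[k, m, n] * X[i + m, n] + b[k]).
    """
    if stride != 1:
        raise ConfigError("stride is fixed at 1")
    single = X.ndim == 2
    Xb = X[None] if single else X
    K, M, N = kernels.shape
    if Xb.shape[1] < M or Xb.shape[2] != N:
        raise ShapeError(
            f"kernel {kernels.shape} incompatible with input {X.shape}"
        )
    windows = sliding_window_view(Xb, (M, N), axis=(1, 2))[:, :, 0]  # (n, P1, M, N)
    z = np.einsum("bimn,kmn->bik", windows, kernels)
    if bias is not None:
        z = z + bias
    out = _relu(z)
    return out[0] if single else out


def init_model(config: ModelConfig, input_shape: tuple[int, int],
               key: tuple[str, int] = ("A", 9)) -> BindingModel:
    """Seeded Glorot-uniform initialization for all layers."""
    P, N_full = input_shape
    N = int(round(N_full * HLA_WINDOW_FRACTIONS[config.hla_window]))
    M = config.kernel_window
    if M > P:
        raise ShapeError(f"kernel window {M} exceeds peptide length {P}")
    P1 = P - M + 1
    M2 = min(config.kernel_window, P1)
    P2 = P1 - M2 + 1
    F = P2 * config.n_kernels2
    rng = np.random.default_rng(config.seed)

    def glorot(shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=shape)

    weights = {
        "W1": glorot((config.n_kernels1, M, N), M * N, config.n_kernels1),
        "W2": glorot((config.n_kernels2, M2, config.n_kernels1),
                     M2 * config.n_kernels1, config.n_kernels2),
        "W3": glorot((config.n_hidden, F), F, config.n_hidden),
        "w4": glorot((config.n_hidden,), config.n_hidden, 1),
        "b1": np.zeros(config.n_kernels1),
        "b2": np.zeros(config.n_kernels2),
        "b3": np.zeros(config.n_hidden),
        "b4": np.zeros(()),
    }
    return BindingModel(config=config, key=key, weights=weights)


def _crop(model: BindingModel, X: np.ndarray) -> np.ndarray:
    """Restrict the HLA axis to the configured window fraction."""
    N = model.weights["W1"].shape[2]
    if X.shape[-1] < N:
        raise ShapeError(f"input HLA axis {X.shape[-1]} narrower than kernels {N}")
    return X[..., :N]


def model_forward(model: BindingModel, X: np.ndarray) -> ForwardTrace:
    """Full forward pass; accepts a single map (P, N) or a batch (n, P, N)."""
    single = X.ndim == 2
    Xb = _crop(model, X[None] if single else np.asarray(X))
    w = model.weights
    A1 = conv_forward(Xb, w["W1"], bias=w["b1"])  # (n, P1, K1)
    A2 = conv_forward(A1, w["W2"], bias=w["b2"])  # (n, P2, K2)
    H = _relu(A2.reshape(len(A2), -1) @ w["W3"].T + w["b3"])  # (n, nh)
    p = _sigmoid(H @ w["w4"] + w["b4"])
    if single:
        return ForwardTrace(conv1=A1[0], conv2=A2[0], hidden=H[0], probability=p[0])
    return ForwardTrace(conv1=A1, conv2=A2, hidden=H, probability=p)


def predict_proba(model: BindingModel, X: np.ndarray) -> np.ndarray:
    return np.atleast_1d(model_forward(model, X).probability)


def objective(model: BindingModel, X: np.ndarray, y: np.ndarray,
              l2_weight: float | None = None, l1_activation: float | None = None,
              max_norm: float | None = None) -> tuple[float, list[str]]:
    """Regularized objective on a batch, plus max-norm constraint violations.

    loss = NLL + l1 * sum(W^2) + l2 * sum|H|  with the likelihood clamped to
    [EPS, 1] for numerical totality.  Violations list every neuron whose
    weight norm exceeds the max-norm bound.
    """
    if len(X) == 0:
        raise ShapeError("empty batch")
    cfg = model.config
    l1 = cfg.l2_weight if l2_weight is None else l2_weight
    l2 = cfg.l1_activation if l1_activation is None else l1_activation
    l3 = cfg.max_norm if max_norm is None else max_norm
    loss, _ = _objective_and_grads(model, _crop(model, X), np.asarray(y, float), l1, l2)
    violations = [
        name for name, norm in _neuron_norms(model.weights) if norm > l3
    ]
    return loss, violations


def _neuron_norms(weights: dict[str, np.ndarray]) -> list[tuple[str, float]]:
    norms = []
    for k in range(len(weights["W1"])):
        norms.append((f"W1[{k}]", float(np.linalg.norm(weights["W1"][k]))))
    for k in range(len(weights["W2"])):
        norms.append((f"W2[{k}]", float(np.linalg.norm(weights["W2"][k]))))
    for r in range(len(weights["W3"])):
        norms.append((f"W3[{r}]", float(np.linalg.norm(weights["W3"][r]))))
    norms.append(("w4", float(np.linalg.norm(weights["w4"]))))
    return norms


def _objective_and_grads(model: BindingModel, X: np.ndarray, y: np.ndarray,
                         l2_weight: float, l1_activation: float
                         ) -> tuple[float, dict[str, np.ndarray]]:
    """Sum-form loss over the batch and its exact analytic gradients."""
    w = model.weights
    W1, W2, W3, w4 = w["W1"], w["W2"], w["W3"], w["w4"]
    K1, M, N = W1.shape
    K2, M2, _ = W2.shape
    n = len(X)

    Xw = sliding_window_view(X, (M, N), axis=(1, 2))[:, :, 0]  # (n, P1, M, N)
    Z1 = np.einsum("bimn,kmn->bik", Xw, W1) + w["b1"]
    A1 = _relu(Z1)  # (n, P1, K1)
    A1w = sliding_window_view(A1, (M2, K1), axis=(1, 2))[:, :, 0]  # (n, P2, M2, K1)
    Z2 = np.einsum("bimc,kmc->bik", A1w, W2) + w["b2"]
    A2 = _relu(Z2)  # (n, P2, K2)
    A2f = A2.reshape(n, -1)
    Z3 = A2f @ W3.T + w["b3"]
    H = _relu(Z3)  # (n, nh)
    z4 = H @ w4 + w["b4"]
    p = _sigmoid(z4)

    q = y * p + (1.0 - y) * (1.0 - p)
    qc = np.maximum(q, EPS)
    if np.any(q < EPS):
        logger.debug("clamped %d likelihood values at EPS", int((q < EPS).sum()))
    nll = float(-np.log(qc).sum())
    reg_w = sum(float((w ** 2).sum()) for w in (W1, W2, W3, w4))
    loss = nll + l2_weight * reg_w + l1_activation * float(np.abs(H).sum())

    # --- backward ---
    active = (q >= EPS).astype(float)
    dz4 = (p - y) * active  # (n,)
    gw4 = H.T @ dz4 + 2.0 * l2_weight * w4
    gb4 = np.asarray(dz4.sum())
    dH = np.outer(dz4, w4) + l1_activation * (H > 0)  # |H| = H on the ReLU range
    dZ3 = dH * (Z3 > 0)
    gW3 = dZ3.T @ A2f + 2.0 * l2_weight * W3
    gb3 = dZ3.sum(axis=0)
    dA2 = (dZ3 @ W3).reshape(A2.shape)
    dZ2 = dA2 * (Z2 > 0)  # (n, P2, K2)
    gW2 = np.einsum("bik,bimc->kmc", dZ2, A1w) + 2.0 * l2_weight * W2
    gb2 = dZ2.sum(axis=(0, 1))
    dA1 = np.zeros_like(A1)
    P2 = Z2.shape[1]
    for m in range(M2):
        dA1[:, m:m + P2, :] += np.einsum("bik,kmc->bic", dZ2, W2[:, m:m + 1, :])
    dZ1 = dA1 * (Z1 > 0)
    gW1 = np.einsum("bik,bimn->kmn", dZ1, Xw) + 2.0 * l2_weight * W1
    gb1 = dZ1.sum(axis=(0, 1))
    return loss, {"W1": gW1, "W2": gW2, "W3": gW3, "w4": gw4,
                  "b1": gb1, "b2": gb2, "b3": gb3, "b4": gb4}


def _project_max_norm(weights: dict[str, np.ndarray], bound: float) -> None:
    """Project every neuron's weight vector onto the L2 ball of radius ``bound``."""
    for key in ("W1", "W2"):
        W = weights[key]
        norms = np.sqrt((W ** 2).sum(axis=tuple(range(1, W.ndim))))
        scale = np.minimum(1.0, bound / np.maximum(norms, EPS))
        W *= scale.reshape(-1, *([1] * (W.ndim - 1)))
    W3 = weights["W3"]
    norms = np.linalg.norm(W3, axis=1)
    W3 *= np.minimum(1.0, bound / np.maximum(norms, EPS))[:, None]
    n4 = np.linalg.norm(weights["w4"])
    if n4 > bound:
        weights["w4"] *= bound / n4


def train(config: ModelConfig, data: TrainingSet,
          callback=None) -> BindingModel:
    """Mini-batch SGD with momentum under the max-norm constraint.

    Gradients of the sum-form objective are averaged over the mini-batch
    before the momentum update; after every update each neuron is projected
    back onto the max-norm ball.  Fully deterministic under ``config.seed``.
    ``callback(model, epoch, batch_loss)`` is invoked after every update.
    """
    if len(np.unique(data.y)) < 2:
        raise DegenerateLabels("training data must contain both classes")
    model = init_model(config, data.X.shape[1:], key=data.key)
    X = _crop(model, data.X)
    y = data.y
    rng = np.random.default_rng(config.seed + 1)
    velocity = {k: np.zeros_like(w) for k, w in model.weights.items()}
    n = len(X)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            # NLL and the activation penalty sum over batch samples and are
            # averaged below; the weight penalty enters once per batch, so it
            # is pre-scaled by the batch size to keep its strength batch-size
            # independent after the division.
            loss, grads = _objective_and_grads(
                model, X[idx], y[idx],
                config.l2_weight * len(idx), config.l1_activation
            )
            for k in model.weights:
                velocity[k] = (config.momentum * velocity[k]
                               - config.learning_rate * grads[k] / len(idx))
                model.weights[k] += velocity[k]
            _project_max_norm(model.weights, config.max_norm)
            if callback is not None:
                callback(model, epoch, loss / len(idx))
    return model


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the Mann-Whitney rank statistic; ties share mid-ranks."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabels("AUC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(scores: Sequence[float], labels: Sequence[int],
             threshold: float = 0.5) -> EvalReport:
    """Rank-based AUC plus F1 at a fixed score threshold (default 0.5)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    auc = roc_auc(scores, labels)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return EvalReport(auc=auc, f1=f1, threshold=threshold,
                      n_pos=int((labels == 1).sum()), n_neg=int((labels == 0).sum()))


def grid_search(base: ModelConfig, grids: dict[str, Sequence],
                train_data: TrainingSet, val_data: TrainingSet) -> ModelConfig:
    """Exhaustive grid search maximizing validation AUC.

    Configurations are enumerated in the lexicographic order of the grids
    (keys in the order given, values in the order listed); ties keep the
    first configuration encountered.
    """
    if len(val_data.y) == 0:
        raise ConfigError("empty validation set")
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ConfigError("grids must be nonempty")
    keys = list(grids)
    best_auc, best_config = -np.inf, None
    for combo in product(*(grids[k] for k in keys)):
        config = replace(base, **dict(zip(keys, combo)))
        model = train(config, train_data)
        auc = roc_auc(predict_proba(model, val_data.X), val_data.y)
        if auc > best_auc:
            best_auc, best_config = auc, config
    return best_config


def save_model(model: BindingModel, path: str) -> None:
    """JSON dump of config + weights; round-trips bit-exactly (repr floats)."""
    payload = {
        "format": "neopred-binding-model-v1",
        "config": asdict(model.config),
        "key": list(model.key),
        "weights": {k: w.tolist() for k, w in model.weights.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> BindingModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "neopred-binding-model-v1":
        raise ConfigError(f"unrecognized model file {path}")
    return BindingModel(
        config=ModelConfig(**payload["config"]),
        key=(payload["key"][0], int(payload["key"][1])),
        weights={k: np.array(v, dtype=float) for k, v in payload["weights"].items()},
    )
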