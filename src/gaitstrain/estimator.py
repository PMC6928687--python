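"""Windowed CNN regressor for joint angles, with weighted multi-output loss.

A four-layer convolutional network maps a 60 x 27 window (9 sensor signals
plus first and second derivatives over 600 ms at 100 Hz) to joint angles in
degrees: 6 outputs for person-specific (intra-participant) models, 3
sagittal outputs for cross-person (inter-participant) models. Kernels are
(3, 1) — they move along the time dimension only — all hidden layers are
ReLU-activated and Xavier-uniform initialized, and training runs mini-batch
Adam with batch size 128 for 10 epochs. Inter-participant training first
draws a 60% bootstrap subsample (with replacement) of the training windows,
as in bagging, and minimizes a per-joint weighted MSE (hip x2, knee x1,
ankle x5); intra-participant training minimizes the plain multi-output MSE.

The network is implemented directly on numpy (im2col convolutions with
manual backpropagation): model capacity is small enough that a deep-learning
framework adds nothing here, and a from-scratch graph keeps CPU training
bit-reproducible from a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "CNNRegressor",
    "mse_loss_intra",
    "mse_loss_inter",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture: 4 conv blocks -> flatten -> dense head -> linear output."""

    conv_filters: tuple[int, ...] = (32, 32, 64, 64)
    kernel: int = 3  # taps along the time axis; (3, 1) in 2-D terms
    dense_widths: tuple[int, ...] = (128,)
    n_outputs: int = 6  # 6 intra, 3 inter
    input_window: int = 60
    input_channels: int = 27

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 4:
            raise ValueError("the regressor uses exactly four convolutional layers")
        t = self.input_window
        for _ in self.conv_filters:
            t -= self.kernel - 1
        if t < 1:
            raise ValueError("window too short for four valid convolutions")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    epochs: int = 10
    subsample_fraction: float = 0.6  # inter-participant bootstrap share
    loss_weights: tuple[float, float, float] = (2.0, 1.0, 5.0)  # hip, knee, ankle
    learning_rate: float = 5e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if any(w <= 0 for w in self.loss_weights):
            raise ValueError("loss weights must be positive")


def mse_loss_intra(pred: np.ndarray, true: np.ndarray) -> float:
    """Multi-output MSE: (1 / (J * N)) * sum over samples and joints."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {true.shape}")
    return float(((pred - true) ** 2).sum() / pred.size)


def mse_loss_inter(
    pred: np.ndarray,
    true: np.ndarray,
    a: float = 2.0,
    b: float = 1.0,
    c: float = 5.0,
) -> float:
    """Weighted sagittal loss A*MSE_hip + B*MSE_knee + C*MSE_ankle.

    Columns are ordered (hip, knee, ankle); each MSE is (1/N) * sum of that
    joint's squared residuals. Hip and ankle are harder to estimate across
    people, hence the asymmetric default weights (2, 1, 5).
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.shape[1] != 3:
        raise ValueError("inter loss expects matching (n, 3) matrices")
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("loss weights must be positive")
    per_joint = ((pred - true) ** 2).mean(axis=0)
    return float(a * per_joint[0] + b * per_joint[1] + c * per_joint[2])


def _xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                    shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class CNNRegressor:
    """Four conv layers (time-axis kernels) + dense head, trained with Adam."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        k = config.kernel
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        self.layer_kinds: list[str] = []

        c_in = config.input_channels
        t = config.input_window
        for f in config.conv_filters:
            self.weights.append(
                _xavier_uniform(rng, k * c_in, k * f, (k * c_in, f))
            )
            self.biases.append(np.zeros(f))
            self.layer_kinds.append("conv")
            c_in = f
            t -= k - 1
        flat = t * c_in
        widths = list(config.dense_widths) + [config.n_outputs]
        d_in = flat
        for i, w in enumerate(widths):
            self.weights.append(_xavier_uniform(rng, d_in, w, (d_in, w)))
            self.biases.append(np.zeros(w))
            self.layer_kinds.append("dense" if i < len(widths) - 1 else "output")
            d_in = w
        self._adam_state: dict | None = None

    # -- forward / backward -------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        # (B, T, C) -> (B, T-k+1, k*C); tap-major channel blocks
        return np.concatenate([x[:, i : x.shape[1] - k + 1 + i, :] for i in range(k)],
                              axis=2)

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Forward pass; ``x`` is (batch, window, channels)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[1:] != (self.config.input_window,
                                          self.config.input_channels):
            raise ValueError(
                f"expected (n, {self.config.input_window}, "
                f"{self.config.input_channels}) input, got {x.shape}"
            )
        k = self.config.kernel
        cache = []
        h = x
        for kind, w, b in zip(self.layer_kinds, self.weights, self.biases):
            if kind == "conv":
                cols = self._im2col(h, k)
                z = cols @ w + b
                a = np.maximum(z, 0.0)
                cache.append(("conv", cols, z, h.shape))
                h = a
            elif kind == "dense":
                if h.ndim == 3:
                    cache.append(("flatten", h.shape, None, None))
                    h = h.reshape(h.shape[0], -1)
                z = h @ w + b
                cache.append(("dense", h, z, None))
                h = np.maximum(z, 0.0)
            else:  # output
                if h.ndim == 3:
                    cache.append(("flatten", h.shape, None, None))
                    h = h.reshape(h.shape[0], -1)
                cache.append(("output", h, None, None))
                h = h @ w + b
        return (h, cache) if keep_cache else h

    def backward(self, cache, dout: np.ndarray):
        """Gradients of all weights/biases given d(loss)/d(output)."""
        k = self.config.kernel
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        li = len(self.weights) - 1
        d = dout
        for item in reversed(cache):
            kind = item[0]
            if kind == "output":
                h = item[1]
                grads_w[li] = h.T @ d
                grads_b[li] = d.sum(axis=0)
                d = d @ self.weights[li].T
                li -= 1
            elif kind == "dense":
                h, z = item[1], item[2]
                d = d * (z > 0)
                grads_w[li] = h.T @ d
                grads_b[li] = d.sum(axis=0)
                d = d @ self.weights[li].T
                li -= 1
            elif kind == "flatten":
                d = d.reshape(item[1])
            elif kind == "conv":
                cols, z, in_shape = item[1], item[2], item[3]
                d = d * (z > 0)
                b_sz, t_out, f = d.shape
                grads_w[li] = cols.reshape(-1, cols.shape[2]).T @ d.reshape(-1, f)
                grads_b[li] = d.sum(axis=(0, 1))
                dcols = d @ self.weights[li].T  # (B, T_out, k*C_in)
                c_in = in_shape[2]
                dx = np.zeros(in_shape)
                for i in range(k):
                    dx[:, i : t_out + i, :] += dcols[:, :, i * c_in : (i + 1) * c_in]
                d = dx
                li -= 1
        return grads_w, grads_b

    # -- optimizer ----------------------------------------------------------

    def adam_step(self, grads_w, grads_b, lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "mw": [np.zeros_like(w) for w in self.weights],
                "vw": [np.zeros_like(w) for w in self.weights],
                "mb": [np.zeros_like(b) for b in self.biases],
                "vb": [np.zeros_like(b) for b in self.biases],
            }
        s = self._adam_state
        s["t"] += 1
        t = s["t"]
        corr1 = 1.0 - beta1**t
        corr2 = 1.0 - beta2**t
        for i in range(len(self.weights)):
            for g, p, m, v in (
                (grads_w[i], self.weights[i], s["mw"][i], s["vw"][i]),
                (grads_b[i], self.biases[i], s["mb"][i], s["vb"][i]),
            ):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                p -= lr * (m / corr1) / (np.sqrt(v / corr2) + eps)


def build_model(config: ModelConfig | None = None, seed: int = 0) -> CNNRegressor:
    """Construct and Xavier-initialize the CNN; deterministic given the seed."""
    return CNNRegressor(config or ModelConfig(), seed=seed)


def _loss_and_grad(pred: np.ndarray, y: np.ndarray, mode: str,
                   weights: tuple[float, float, float]):
    r = pred - y
    n = pred.shape[0]
    if mode == "intra":
        loss = float((r**2).sum() / r.size)
        grad = 2.0 * r / r.size
    elif mode == "inter":
        w = np.asarray(weights, dtype=float)
        per_joint = (r**2).mean(axis=0)
        loss = float((w * per_joint).sum())
        grad = 2.0 * w * r / n
    else:
        raise ValueError("mode must be 'intra' or 'inter'")
    return loss, grad


def train(
    model: CNNRegressor,
    windows,
    tc: TrainConfig | None = None,
    mode: str = "intra",
) -> tuple[CNNRegressor, list[float]]:
    """Train in place; returns the model and the per-epoch mean training loss.

    ``windows`` is a :class:`~gaitstrain.preprocessing.WindowBatch` (or any
    object with ``x`` (n, 60, 27) and ``y`` (n, outputs)). Inter mode first
    draws one bootstrap subsample of round(subsample_fraction * n) windows
    with replacement and minimizes the weighted sagittal loss; intra mode
    uses all windows and the plain multi-output MSE. The output bias is
    initialized to the training-target channel means so the 10-epoch budget
    is spent on the angle dynamics rather than on locating their offsets.
    """
    tc = tc or TrainConfig()
    x = np.asarray(windows.x, dtype=float)
    y = np.asarray(windows.y, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if y.shape[1] != model.config.n_outputs:
        raise ValueError(
            f"model has {model.config.n_outputs} outputs but targets have "
            f"{y.shape[1]} columns"
        )
    rng = np.random.default_rng(tc.seed)
    if mode == "inter":
        n_sub = int(round(tc.subsample_fraction * x.shape[0]))
        pick = rng.integers(0, x.shape[0], size=n_sub)  # with replacement
        x, y = x[pick], y[pick]
    model.biases[-1] = y.mean(axis=0)

    history: list[float] = []
    n = x.shape[0]
    for _ in range(tc.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            pred, cache = model.forward(x[idx], keep_cache=True)
            loss, dout = _loss_and_grad(pred, y[idx], mode, tc.loss_weights)
            gw, gb = model.backward(cache, dout)
            model.adam_step(gw, gb, tc.learning_rate)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return model, history


def predict(model: CNNRegressor, windows, batch_size: int = 1024) -> np.ndarray:
    """Batched deterministic inference; one angle vector per window (degrees)."""
    x = windows if isinstance(windows, np.ndarray) else windows.x
    outs = [
        model.forward(x[i : i + batch_size])
        for i in range(0, x.shape[0], batch_size)
    ]
    return np.concatenate(outs, axis=0) if outs else np.empty((0, model.config.n_outputs))


def save_model(model: CNNRegressor, path: str | Path) -> None:
    """Weights as .npz with a JSON sidecar of the configuration and seed."""
    path = Path(path)
    arrays = {}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"model_config": asdict(model.config), "seed": model.seed}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> CNNRegressor:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = sidecar["model_config"]
    cfg["conv_filters"] = tuple(cfg["conv_filters"])
    cfg["dense_widths"] = tuple(cfg["dense_widths"])
    model = CNNRegressor(ModelConfig(**cfg), seed=sidecar["seed"])
    data = np.load(path.with_suffix(".npz"))
    for i in range(len(model.weights)):
        model.weights[i] = data[f"w{i}"]
        model.biases[i] = data[f"b{i}"]
    return model
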