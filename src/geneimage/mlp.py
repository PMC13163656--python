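"""Full-synapse three-layer sigmoid network with online backpropagation.

The network is the recognizer of genetic images: n input units (one per bit),
a hidden layer sized by the geometric pyramid rule sqrt(n*k), and k sigmoid
outputs, one per organism in the teaching set. Training is plain per-sample
(online) backpropagation with momentum, stopped when the root-mean-squared
error over all samples and outputs reaches a target (0.01 by default).

Unstated framework details are fixed here as: bias units on both layers,
uniform [-0.5, 0.5] seeded weight initialization, and seeded reshuffling of
the presentation order each epoch (a fixed order is available via
``shuffle_each_epoch=False``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MLPConfig",
    "MLPModel",
    "NonConvergenceError",
    "hidden_size",
    "init_mlp",
    "forward",
    "rmse",
    "train_online",
    "save_model",
    "load_model",
]


class NonConvergenceError(RuntimeError):
    """Raised when training hits the epoch cap above the target RMSE."""

    def __init__(self, seed: int, final_rmse: float, epochs: int,
                 log: list[float] | None = None):
        self.seed = seed
        self.final_rmse = final_rmse
        self.epochs = epochs
        self.log = log or []
        super().__init__(
            f"no convergence after {epochs} epochs (seed {seed}): "
            f"RMSE {final_rmse:.5f} above target"
        )


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and teaching hyper-parameters of one network.

    Defaults follow the single-gene setting (learning rate 0.3, momentum 0.1);
    the concatenated-image setting uses 0.07 for both. ``target_rmse`` is the
    stopping criterion over all samples and outputs.
    """

    n_inputs: int
    n_outputs: int
    n_hidden: int | None = None
    learning_rate: float = 0.3
    momentum: float = 0.1
    target_rmse: float = 0.01
    max_epochs: int = 50_000
    seed: int = 0
    shuffle_each_epoch: bool = True

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_outputs < 1:
            raise ValueError("n_inputs and n_outputs must be >= 1")
        if self.n_hidden is not None and self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if not 0 < self.target_rmse < 1:
            raise ValueError("target_rmse must lie in (0, 1)")
        if self.learning_rate < 0 or self.momentum < 0:
            raise ValueError("learning_rate and momentum must be >= 0")

    def resolved_hidden(self) -> int:
        if self.n_hidden is not None:
            return self.n_hidden
        return hidden_size(self.n_inputs, self.n_outputs)


@dataclass
class MLPModel:
    """Weights of one trained or untrained network.

    Weight matrices carry the bias as their last column, so shapes are
    hidden (n_hidden, n_inputs+1) and output (n_outputs, n_hidden+1).
    """

    config: MLPConfig
    hidden_weights: np.ndarray
    output_weights: np.ndarray
    label_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        nh = self.config.resolved_hidden()
        if self.hidden_weights.shape != (nh, self.config.n_inputs + 1):
            raise ValueError("hidden_weights shape inconsistent with config")
        if self.output_weights.shape != (self.config.n_outputs, nh + 1):
            raise ValueError("output_weights shape inconsistent with config")
        if self.label_order and len(self.label_order) != self.config.n_outputs:
            raise ValueError("label_order length must equal n_outputs")


def hidden_size(n: int, k: int) -> int:
    """Geometric pyramid rule: round(sqrt(n*k)), at least 1."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    return max(1, round(float(np.sqrt(n * k))))


def init_mlp(config: MLPConfig, label_order: list[str] | None = None) -> MLPModel:
    """Fresh model with weights drawn uniformly from [-0.5, 0.5] (seeded)."""
    rng = np.random.default_rng(config.seed)
    nh = config.resolved_hidden()
    hw = rng.uniform(-0.5, 0.5, size=(nh, config.n_inputs + 1))
    ow = rng.uniform(-0.5, 0.5, size=(config.n_outputs, nh + 1))
    return MLPModel(config=config, hidden_weights=hw, output_weights=ow,
                    label_order=list(label_order or []))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _forward_layers(model: MLPModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h = _sigmoid(model.hidden_weights[:, :-1] @ x + model.hidden_weights[:, -1])
    y = _sigmoid(model.output_weights[:, :-1] @ h + model.output_weights[:, -1])
    return h, y


def forward(model: MLPModel, input_bits: np.ndarray) -> np.ndarray:
    """Activations of the output layer for one genetic image; all in (0, 1)."""
    x = np.asarray(input_bits, dtype=float)
    if x.shape != (model.config.n_inputs,):
        raise ValueError(
            f"input length {x.size} does not match n_inputs {model.config.n_inputs}"
        )
    return _forward_layers(model, x)[1]


def rmse(model: MLPModel, samples: list[np.ndarray], targets: list[np.ndarray]) -> float:
    """Root-mean-squared error over all samples and all output units."""
    if not samples:
        raise ValueError("empty sample list")
    if len(samples) != len(targets):
        raise ValueError("samples and targets differ in length")
    sq = 0.0
    count = 0
    for x, t in zip(samples, targets):
        y = forward(model, x)
        sq += float(np.sum((y - np.asarray(t, dtype=float)) ** 2))
        count += y.size
    return float(np.sqrt(sq / count))


def _run_epochs_numpy(
    hw: np.ndarray,
    ow: np.ndarray,
    d_hw: np.ndarray,
    d_ow: np.ndarray,
    xs: np.ndarray,
    ts: np.ndarray,
    orders: np.ndarray,
    lr: float,
    mom: float,
    target_rmse: float,
) -> tuple[np.ndarray, int]:
    """Run a chunk of epochs in place; stop early once RMSE <= target.

    Returns (per-epoch RMSE values, number of epochs actually run).
    """
    n_epochs, n_samples = orders.shape
    log = np.empty(n_epochs)
    for e in range(n_epochs):
        for i in orders[e]:
            x, t = xs[i], ts[i]
            h = _sigmoid(hw[:, :-1] @ x + hw[:, -1])
            y = _sigmoid(ow[:, :-1] @ h + ow[:, -1])
            # squared-error deltas through the sigmoid derivatives
            delta_o = (t - y) * y * (1.0 - y)
            delta_h = (ow[:, :-1].T @ delta_o) * h * (1.0 - h)
            d_ow *= mom
            d_ow[:, :-1] += lr * np.outer(delta_o, h)
            d_ow[:, -1] += lr * delta_o
            d_hw *= mom
            d_hw[:, :-1] += lr * np.outer(delta_h, x)
            d_hw[:, -1] += lr * delta_h
            ow += d_ow
            hw += d_hw
        sq = 0.0
        for i in range(n_samples):
            h = _sigmoid(hw[:, :-1] @ xs[i] + hw[:, -1])
            y = _sigmoid(ow[:, :-1] @ h + ow[:, -1])
            sq += float(np.sum((y - ts[i]) ** 2))
        log[e] = np.sqrt(sq / (n_samples * ow.shape[0]))
        if log[e] <= target_rmse:
            return log, e + 1
    return log, n_epochs


try:  # JIT-compiled inner loop; arithmetic identical to the numpy path
    import numba as _numba

    @_numba.njit(cache=False)
    def _run_epochs_jit(hw, ow, d_hw, d_ow, xs, ts, orders, lr, mom, target_rmse):
        n_epochs, n_samples = orders.shape
        nh, nin1 = hw.shape
        k, nh1 = ow.shape
        nin = nin1 - 1
        h = np.empty(nh)
        y = np.empty(k)
        delta_o = np.empty(k)
        delta_h = np.empty(nh)
        log = np.empty(n_epochs)
        for e in range(n_epochs):
            for s in range(n_samples):
                i = orders[e, s]
                x = xs[i]
                t = ts[i]
                for j in range(nh):
                    acc = hw[j, nin]
                    for m in range(nin):
                        acc += hw[j, m] * x[m]
                    h[j] = 1.0 / (1.0 + np.exp(-acc))
                for o in range(k):
                    acc = ow[o, nh]
                    for j in range(nh):
                        acc += ow[o, j] * h[j]
                    y[o] = 1.0 / (1.0 + np.exp(-acc))
                for o in range(k):
                    delta_o[o] = (t[o] - y[o]) * y[o] * (1.0 - y[o])
                for j in range(nh):
                    acc = 0.0
                    for o in range(k):
                        acc += ow[o, j] * delta_o[o]
                    delta_h[j] = acc * h[j] * (1.0 - h[j])
                for o in range(k):
                    for j in range(nh):
                        d_ow[o, j] = mom * d_ow[o, j] + lr * delta_o[o] * h[j]
                        ow[o, j] += d_ow[o, j]
                    d_ow[o, nh] = mom * d_ow[o, nh] + lr * delta_o[o]
                    ow[o, nh] += d_ow[o, nh]
                for j in range(nh):
                    for m in range(nin):
                        d_hw[j, m] = mom * d_hw[j, m] + lr * delta_h[j] * x[m]
                        hw[j, m] += d_hw[j, m]
                    d_hw[j, nin] = mom * d_hw[j, nin] + lr * delta_h[j]
                    hw[j, nin] += d_hw[j, nin]
            sq = 0.0
            for i in range(n_samples):
                x = xs[i]
                for j in range(nh):
                    acc = hw[j, nin]
                    for m in range(nin):
                        acc += hw[j, m] * x[m]
                    h[j] = 1.0 / (1.0 + np.exp(-acc))
                for o in range(k):
                    acc = ow[o, nh]
                    for j in range(nh):
                        acc += ow[o, j] * h[j]
                    yo = 1.0 / (1.0 + np.exp(-acc))
                    sq += (yo - ts[i, o]) ** 2
            log[e] = np.sqrt(sq / (n_samples * k))
            if log[e] <= target_rmse:
                return log, e + 1
        return log, n_epochs

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False

_EPOCH_CHUNK = 200


def train_online(
    model: MLPModel,
    samples: list[np.ndarray],
    targets: list[np.ndarray],
    config: MLPConfig | None = None,
) -> tuple[MLPModel, list[float]]:
    """Teach by per-sample backpropagation with momentum until RMSE target.

    Returns the trained model and the per-epoch RMSE log. Raises
    :class:`NonConvergenceError` at the epoch cap. Each weight update is
    ``dW <- lr * gradient + momentum * dW_prev`` applied immediately after
    its sample's forward pass; the epoch-end RMSE over all samples and
    outputs is the stopping criterion.
    """
    cfg = config or model.config
    if len(samples) != len(targets):
        raise ValueError("samples and targets differ in length")
    hot = [int(np.argmax(t)) for t in targets]
    if len(set(hot)) != len(hot):
        raise ValueError("each sample's one-hot index must be unique")
    xs = np.asarray(samples, dtype=float)
    ts = np.asarray(targets, dtype=float)
    n_samples = len(samples)

    rng = np.random.default_rng(cfg.seed)
    hw = np.ascontiguousarray(model.hidden_weights, dtype=float).copy()
    ow = np.ascontiguousarray(model.output_weights, dtype=float).copy()
    d_hw = np.zeros_like(hw)
    d_ow = np.zeros_like(ow)

    runner = _run_epochs_jit if _HAVE_NUMBA else _run_epochs_numpy
    log: list[float] = []
    epochs_left = cfg.max_epochs
    while epochs_left > 0:
        chunk = min(_EPOCH_CHUNK, epochs_left)
        if cfg.shuffle_each_epoch:
            orders = np.stack([rng.permutation(n_samples) for _ in range(chunk)])
        else:
            orders = np.tile(np.arange(n_samples), (chunk, 1))
        chunk_log, ran = runner(
            hw, ow, d_hw, d_ow, xs, ts, orders,
            cfg.learning_rate, cfg.momentum, cfg.target_rmse,
        )
        log.extend(float(v) for v in chunk_log[:ran])
        epochs_left -= ran
        if log[-1] <= cfg.target_rmse:
            return MLPModel(cfg, hw, ow, list(model.label_order)), log
    raise NonConvergenceError(
        cfg.seed, log[-1] if log else float("nan"), cfg.max_epochs, log
    )


def save_model(model: MLPModel, path: str | Path) -> None:
    """Serialize config + labels as JSON and weights as .npz next to it."""
    path = Path(path)
    meta = {
        "format": "geneimage-mlp-v1",
        "config": {
            "n_inputs": model.config.n_inputs,
            "n_outputs": model.config.n_outputs,
            "n_hidden": model.config.resolved_hidden(),
            "learning_rate": model.config.learning_rate,
            "momentum": model.config.momentum,
            "target_rmse": model.config.target_rmse,
            "max_epochs": model.config.max_epochs,
            "seed": model.config.seed,
            "shuffle_each_epoch": model.config.shuffle_each_epoch,
        },
        "label_order": model.label_order,
    }
    path.write_text(json.dumps(meta, indent=2))
    np.savez(
        path.with_suffix(".weights.npz"),
        hidden=model.hidden_weights,
        output=model.output_weights,
    )


def load_model(path: str | Path) -> MLPModel:
    """Inverse of :func:`save_model`; exact round trip."""
    path = Path(path)
    meta = json.loads(path.read_text())
    if meta.get("format") != "geneimage-mlp-v1":
        raise ValueError(f"unrecognized model file {path}")
    cfg = MLPConfig(**meta["config"])
    with np.load(path.with_suffix(".weights.npz")) as npz:
        return MLPModel(
            config=cfg,
            hidden_weights=npz["hidden"],
            output_weights=npz["output"],
            label_order=list(meta["label_order"]),
        )
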