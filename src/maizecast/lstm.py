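"""Many-to-one stacked LSTM regressor, in plain NumPy.

The network consumes a standardized multivariate daily sequence and emits one
scalar: the de-trended county yield.  Gates follow the standard formulation

    i_t = sigmoid(W_i h_{t-1} + U_i x_t + b_i)
    f_t = sigmoid(W_f h_{t-1} + U_f x_t + b_f)
    o_t = sigmoid(W_o h_{t-1} + U_o x_t + b_o)
    g_t = tanh   (W_c h_{t-1} + U_c x_t + b_c)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

with W recurrent (d x d), U input (d x k), b bias (d).  Layers stack; a
linear map on the top layer's final hidden state produces the prediction.
Training minimizes mean squared error by mini-batch gradient descent with
exact backpropagation-through-time gradients (verified against finite
differences in the test suite), using either SGD with momentum and learning
rate decay or RMSprop (learning rate only).

Targets are z-scored internally (statistics stored on the parameters and
inverted on output): the optimizers take steps of order the learning rate,
so an output bias would otherwise need ~1e5 updates to reach the ~180 bu/ac
scale of de-trended yields.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit as _sigmoid

__all__ = [
    "LSTMLayerParams",
    "ModelParams",
    "TrainConfig",
    "SearchSpace",
    "TrainingDiverged",
    "init_params",
    "lstm_cell_step",
    "lstm_forward",
    "forward_batch",
    "backward_batch",
    "loss_and_gradients",
    "train",
    "random_search",
]

_CHUNK = 256  # cap on samples processed per BPTT pass, bounds peak memory


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class LSTMLayerParams:
    """One layer's gate parameters, rows stacked in (i, f, o, c~) order."""

    W: np.ndarray  # (4d, d) recurrent
    U: np.ndarray  # (4d, k) input
    b: np.ndarray  # (4d,)

    @property
    def hidden(self) -> int:
        return self.W.shape[1]

    @property
    def input_size(self) -> int:
        return self.U.shape[1]

    def validate(self) -> None:
        d = self.hidden
        if self.W.shape != (4 * d, d) or self.U.shape[0] != 4 * d or self.b.shape != (4 * d,):
            raise ValueError("inconsistent layer parameter shapes")
        for a in (self.W, self.U, self.b):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite layer parameters")


@dataclass
class ModelParams:
    """Full model: stacked layers, linear output map, and target scaling."""

    layers: list[LSTMLayerParams]
    v: np.ndarray              # (d_top,) output weights
    b_out: np.ndarray          # shape-() output bias
    dropout: float = 0.0
    channel_names: tuple[str, ...] = ()
    n_time: int | None = None
    target_mean: float = 0.0
    target_sd: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi in zip(self.layers[:-1], self.layers[1:]):
            if hi.input_size != lo.hidden:
                raise ValueError("layer input size must equal the previous hidden size")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def n_params(self) -> int:
        n = self.v.size + 1
        for l in self.layers:
            n += l.W.size + l.U.size + l.b.size
        return n

    def arrays(self) -> list[np.ndarray]:
        """Flat parameter list in a fixed order (optimizers index into this)."""
        out = []
        for l in self.layers:
            out.extend([l.W, l.U, l.b])
        out.extend([self.v, self.b_out])
        return out


def init_params(
    n_vars: int,
    hidden: int,
    n_layers: int = 2,
    dropout: float = 0.0,
    seed: int = 0,
    channel_names: tuple[str, ...] = (),
    n_time: int | None = None,
    dtype=np.float64,
) -> ModelParams:
    """Small-uniform initialization (+-1/sqrt(fan-in)); forget bias starts at 1."""
    rng = np.random.default_rng(seed)
    layers = []
    k = n_vars
    for _ in range(n_layers):
        d = hidden
        W = rng.uniform(-1, 1, (4 * d, d)) / np.sqrt(d)
        U = rng.uniform(-1, 1, (4 * d, k)) / np.sqrt(k)
        b = np.zeros(4 * d)
        b[d : 2 * d] = 1.0  # open the forget gate so early gradients flow
        layers.append(LSTMLayerParams(W.astype(dtype), U.astype(dtype), b.astype(dtype)))
        k = d
    v = (rng.uniform(-1, 1, hidden) / np.sqrt(hidden)).astype(dtype)
    return ModelParams(
        layers=layers,
        v=v,
        b_out=np.zeros((), dtype=dtype),
        dropout=dropout,
        channel_names=tuple(channel_names),
        n_time=n_time,
    )


def lstm_cell_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, layer: LSTMLayerParams
) -> tuple[np.ndarray, np.ndarray]:
    """One cell update for a single sample; returns (h_t, c_t)."""
    x_t, h_prev, c_prev = (np.asarray(a, dtype=float) for a in (x_t, h_prev, c_prev))
    d = layer.hidden
    if x_t.shape != (layer.input_size,) or h_prev.shape != (d,) or c_prev.shape != (d,):
        raise ValueError(
            f"shape mismatch: x {x_t.shape}, h {h_prev.shape}, c {c_prev.shape} "
            f"for layer (d={d}, k={layer.input_size})"
        )
    z = layer.W @ h_prev + layer.U @ x_t + layer.b
    i, f, o = _sigmoid(z[:d]), _sigmoid(z[d : 2 * d]), _sigmoid(z[2 * d : 3 * d])
    g = np.tanh(z[3 * d :])
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def forward_batch(
    X: np.ndarray,
    params: ModelParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
    keep_cache: bool = False,
):
    """Batched forward pass.

    ``X`` has shape (B, T, k).  Returns predictions in target-standardized
    units, plus the cache needed by :func:`backward_batch` when requested.
    Dropout (inverted, one mask per sample shared across time) applies to
    each layer's output only when ``training``.
    """
    B, T, _ = X.shape
    if params.n_time is not None and T != params.n_time:
        raise ValueError(f"model expects sequences of length {params.n_time}, got {T}")
    cache = {"layers": [], "X": X}
    inp = X
    for layer in params.layers:
        d = layer.hidden
        ZX = inp @ layer.U.T + layer.b  # (B, T, 4d)
        H = np.zeros((T + 1, B, d), dtype=X.dtype)
        C = np.zeros((T + 1, B, d), dtype=X.dtype)
        gates = np.empty((T, B, 4 * d), dtype=X.dtype)
        WT = layer.W.T
        for t in range(T):
            z = ZX[:, t, :] + H[t] @ WT
            zs = _sigmoid(z[:, : 3 * d])
            zg = np.tanh(z[:, 3 * d :])
            i, f = zs[:, :d], zs[:, d : 2 * d]
            o = zs[:, 2 * d : 3 * d]
            C[t + 1] = f * C[t] + i * zg
            H[t + 1] = o * np.tanh(C[t + 1])
            gates[t, :, : 3 * d] = zs
            gates[t, :, 3 * d :] = zg
        # contiguous copy: a strided view would force slow non-BLAS matmuls upstream
        out = np.ascontiguousarray(np.transpose(H[1:], (1, 0, 2)))  # (B, T, d)
        if training and params.dropout > 0:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            keep = 1.0 - params.dropout
            mask = (rng.random((B, 1, d)) < keep) / keep
            out = out * mask
        else:
            mask = None
        cache["layers"].append({"input": inp, "H": H, "C": C, "gates": gates, "mask": mask})
        inp = out
    pred = inp[:, -1, :] @ params.v + params.b_out
    cache["top_out"] = inp
    return (pred, cache) if keep_cache else pred


def backward_batch(dpred: np.ndarray, params: ModelParams, cache) -> list[np.ndarray]:
    """Exact BPTT gradients for every parameter array, matching ``arrays()`` order."""
    B = dpred.shape[0]
    top = cache["top_out"]
    dv = top[:, -1, :].T @ dpred
    db_out = np.asarray(dpred.sum())
    T = top.shape[1]
    d_top = params.layers[-1].hidden
    # time-major throughout: dOut[t] is the gradient w.r.t. the layer output at step t
    dOut = np.zeros((T, B, d_top), dtype=top.dtype)
    dOut[-1] = np.outer(dpred, params.v)

    layer_grads: list[list[np.ndarray]] = []
    for layer, lc in zip(reversed(params.layers), reversed(cache["layers"])):
        d = layer.hidden
        H, C, gates = lc["H"], lc["C"], lc["gates"]
        if lc["mask"] is not None:
            dOut = dOut * np.transpose(lc["mask"], (1, 0, 2))
        dZ = np.empty_like(gates)  # (T, B, 4d)
        dh = np.zeros((B, d), dtype=gates.dtype)
        dc = np.zeros((B, d), dtype=gates.dtype)
        for t in range(T - 1, -1, -1):
            dh = dh + dOut[t]
            i = gates[t, :, :d]
            f = gates[t, :, d : 2 * d]
            o = gates[t, :, 2 * d : 3 * d]
            g = gates[t, :, 3 * d :]
            tc = np.tanh(C[t + 1])
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * C[t]
            dZ[t, :, :d] = di * i * (1.0 - i)
            dZ[t, :, d : 2 * d] = df * f * (1.0 - f)
            dZ[t, :, 2 * d : 3 * d] = do * o * (1.0 - o)
            dZ[t, :, 3 * d :] = dg * (1.0 - g * g)
            dh = dZ[t] @ layer.W
            dc = dc * f
        flatZ = dZ.reshape(T * B, 4 * d)
        dW = flatZ.T @ H[:-1].reshape(T * B, d)
        dU = flatZ.T @ np.ascontiguousarray(lc["input"].transpose(1, 0, 2)).reshape(T * B, -1)
        db = flatZ.sum(axis=0)
        layer_grads.append([dW, dU, db])
        if len(layer_grads) < len(params.layers):
            # gradient w.r.t. the layer below's output, stays time-major
            dOut = (flatZ @ layer.U).reshape(T, B, -1)

    grads: list[np.ndarray] = []
    for g3 in reversed(layer_grads):
        grads.extend(g3)
    grads.extend([dv, db_out])
    return grads


def loss_and_gradients(
    X: np.ndarray,
    y_std: np.ndarray,
    params: ModelParams,
    training: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, list[np.ndarray]]:
    """Mean squared error over the batch and its parameter gradients.

    Large batches are processed in fixed-size chunks (gradients accumulate
    exactly) to bound peak memory at wide hidden sizes.
    """
    B = X.shape[0]
    total_loss = 0.0
    grads: list[np.ndarray] | None = None
    for start in range(0, B, _CHUNK):
        Xc = X[start : start + _CHUNK]
        yc = y_std[start : start + _CHUNK]
        pred, cache = forward_batch(Xc, params, training=training, rng=rng, keep_cache=True)
        err = pred - yc
        total_loss += float(err @ err)
        dpred = (2.0 / B) * err
        g = backward_batch(dpred, params, cache)
        if grads is None:
            grads = g
        else:
            for a, b in zip(grads, g):
                a += b
    return total_loss / B, grads


@dataclass
class TrainConfig:
    """Optimization settings; defaults suit the synthetic study scale."""

    hidden: int = 32
    n_layers: int = 2
    batch_size: int = 64
    dropout: float = 0.1
    learning_rate: float = 1e-3
    momentum: float = 0.0   # SGD only
    decay: float = 0.0      # SGD only: lr_t = lr / (1 + decay * t)
    optimizer: str = "rmsprop"
    epochs: int = 40
    patience: int | None = 8

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "rmsprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class _Optimizer:
    def __init__(self, cfg: TrainConfig, arrays: list[np.ndarray]):
        self.cfg = cfg
        self.state = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        cfg = self.cfg
        self.t += 1
        if cfg.optimizer == "sgd":
            lr = cfg.learning_rate / (1.0 + cfg.decay * self.t)
            for p, g, v in zip(arrays, grads, self.state):
                v *= cfg.momentum
                v -= lr * g
                p += v
        else:  # rmsprop: moving average of squared gradients normalizes the step
            rho, eps = 0.9, 1e-7
            for p, g, a in zip(arrays, grads, self.state):
                a *= rho
                a += (1.0 - rho) * g * g
                p -= cfg.learning_rate * g / (np.sqrt(a) + eps)


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    channel_names: tuple[str, ...] = (),
    standardize_target: bool = True,
    dtype=np.float64,
) -> tuple[ModelParams, pd.DataFrame]:
    """Fit the LSTM on standardized sequences X (n, T, k) and de-trended targets y.

    Deterministic given (config, seed, data).  Returns the fitted parameters
    (best-validation snapshot when a validation set and patience are given)
    and a per-epoch history of train/validation MSE in original target units.
    Raises :class:`TrainingDiverged` if the loss goes non-finite.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=dtype)
    y = np.asarray(y, dtype=np.float64)
    n, T, k = X.shape
    if standardize_target:
        t_mean, t_sd = float(y.mean()), float(y.std())
        t_sd = t_sd if t_sd > 0 else 1.0
    else:
        t_mean, t_sd = 0.0, 1.0
    y_std = (y - t_mean) / t_sd

    params = init_params(
        k,
        config.hidden,
        config.n_layers,
        config.dropout,
        seed=int(rng.integers(2**31)),
        channel_names=channel_names,
        n_time=T,
        dtype=dtype,
    )
    params.target_mean, params.target_sd = t_mean, t_sd
    opt = _Optimizer(config, params.arrays())

    have_val = X_val is not None and y_val is not None
    if have_val:
        X_val = np.asarray(X_val, dtype=dtype)
        yv_std = (np.asarray(y_val, dtype=np.float64) - t_mean) / t_sd

    history = []
    best_val, best_snapshot, stale = np.inf, None, 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = loss_and_gradients(X[idx], y_std[idx], params, training=True, rng=rng)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} (config={config})"
                )
            opt.step(params.arrays(), grads)
            epoch_loss += loss
            n_batches += 1
        train_mse = (epoch_loss / n_batches) * t_sd**2
        row = {"epoch": epoch, "train_mse": train_mse, "val_mse": np.nan}
        if have_val:
            pv = _predict_std(X_val, params)
            val_mse = float(np.mean((pv - yv_std) ** 2)) * t_sd**2
            row["val_mse"] = val_mse
            if val_mse < best_val - 1e-12:
                best_val, stale = val_mse, 0
                best_snapshot = copy.deepcopy(params)
            else:
                stale += 1
                if config.patience is not None and stale >= config.patience:
                    history.append(row)
                    break
        history.append(row)
    if best_snapshot is not None:
        params = best_snapshot
    return params, pd.DataFrame(history)


def _predict_std(X: np.ndarray, params: ModelParams) -> np.ndarray:
    """Inference-mode predictions in standardized target units, chunked."""
    out = []
    for start in range(0, X.shape[0], _CHUNK):
        out.append(forward_batch(X[start : start + _CHUNK], params, training=False))
    return np.concatenate(out)


def predict(X: np.ndarray, params: ModelParams) -> np.ndarray:
    """De-trended (base-year bu/ac scale) predictions for sequences X (n, T, k)."""
    X = np.asarray(X, dtype=params.v.dtype)
    return _predict_std(X, params) * params.target_sd + params.target_mean


def lstm_forward(sequence: np.ndarray, params: ModelParams, training: bool = False,
                 rng: np.random.Generator | None = None) -> float:
    """Forward pass for one sequence of shape (n_vars, n_time)."""
    sequence = np.asarray(sequence, dtype=float)
    if params.channel_names and sequence.shape[0] != len(params.channel_names):
        raise ValueError(
            f"sequence has {sequence.shape[0]} channels; model expects "
            f"{len(params.channel_names)}"
        )
    X = sequence.T[None, :, :]
    raw = forward_batch(X, params, training=training, rng=rng)[0]
    return float(raw * params.target_sd + params.target_mean)


@dataclass(frozen=True)
class SearchSpace:
    """Random-search choice sets for the hyperparameters."""

    hidden_nodes: tuple[int, ...] = (8, 16, 32, 64, 128, 214)
    batch_size: tuple[int, ...] = (16, 64, 128, 512, 1024)
    dropout: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
    learning_rate: tuple[float, ...] = (1e-7, 1e-6, 1e-5, 1e-4, 0.001)
    momentum: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.05, 0.1)
    decay: tuple[float, ...] = (0.0001, 0.001, 0.01, 0.05, 0.1)
    optimizers: tuple[str, ...] = ("sgd", "rmsprop")

    def sample(self, rng: np.random.Generator, epochs: int, patience: int | None) -> TrainConfig:
        pick = lambda choices: choices[rng.integers(len(choices))]
        return TrainConfig(
            hidden=int(pick(self.hidden_nodes)),
            batch_size=int(pick(self.batch_size)),
            dropout=float(pick(self.dropout)),
            learning_rate=float(pick(self.learning_rate)),
            momentum=float(pick(self.momentum)),
            decay=float(pick(self.decay)),
            optimizer=str(pick(self.optimizers)),
            epochs=epochs,
            patience=patience,
        )


def random_search(
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    space: SearchSpace,
    budget: int,
    seed: int = 0,
    epochs: int = 6,
    patience: int | None = 3,
    dtype=np.float64,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Sample ``budget`` configurations, train each briefly, rank by validation MSE.

    A configuration whose loss diverges is kept on the leaderboard with an
    infinite score rather than aborting the search.  Deterministic given seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    best_cfg, best_val = None, np.inf
    for trial in range(budget):
        cfg = space.sample(rng, epochs=epochs, patience=patience)
        train_seed = int(rng.integers(2**31))
        try:
            params, history = train(
                X, y, cfg, seed=train_seed, X_val=X_val, y_val=y_val, dtype=dtype
            )
            val_mse = float(np.nanmin(history["val_mse"]))
        except TrainingDiverged:
            val_mse = np.inf
        rows.append(
            {
                "trial": trial,
                "val_mse": val_mse,
                "hidden": cfg.hidden,
                "batch_size": cfg.batch_size,
                "dropout": cfg.dropout,
                "learning_rate": cfg.learning_rate,
                "momentum": cfg.momentum,
                "decay": cfg.decay,
                "optimizer": cfg.optimizer,
                "train_seed": train_seed,
            }
        )
        if val_mse < best_val:
            best_val, best_cfg = val_mse, cfg
    leaderboard = pd.DataFrame(rows).sort_values("val_mse", kind="stable").reset_index(drop=True)
    return best_cfg, leaderboard
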