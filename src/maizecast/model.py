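"""Model/Results interface over the LSTM core.

`YieldLSTM` is constructed from a training cube (and optionally a validation
cube); `fit()` returns a `YieldLSTMResults` carrying the fitted parameters,
the loss history, and prediction/summary methods.  `search()` runs the
random hyperparameter search and returns the winning configuration plus the
leaderboard.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import lstm
from .cube import FeatureCube
from .lstm import ModelParams, SearchSpace, TrainConfig

__all__ = ["YieldLSTM", "YieldLSTMResults"]


def _targets(cube: FeatureCube) -> np.ndarray:
    if cube.targets is None or not np.all(np.isfinite(cube.targets)):
        raise ValueError("cube must carry finite de-trended targets")
    return cube.targets


class YieldLSTM:
    """Many-to-one LSTM yield model bound to a training cube.

    Parameters
    ----------
    train_cube : FeatureCube
        Standardization-bearing cube of training samples with de-trended
        targets (bu/ac at the base-year scale).
    config : TrainConfig, optional
        Optimization settings; defaults are the package defaults.
    val_cube : FeatureCube, optional
        Held-out samples used for early stopping and for ranking
        hyperparameter search trials.
    """

    def __init__(
        self,
        train_cube: FeatureCube,
        config: TrainConfig | None = None,
        val_cube: FeatureCube | None = None,
        dtype=np.float64,
    ):
        self.train_cube = train_cube
        self.val_cube = val_cube
        self.config = config or TrainConfig()
        self.dtype = dtype
        self._X = train_cube.standardized().astype(dtype)
        self._y = _targets(train_cube)
        if val_cube is not None:
            self._Xv = self._standardize_like_train(val_cube)
            self._yv = _targets(val_cube)
        else:
            self._Xv = self._yv = None

    @classmethod
    def from_cube(
        cls,
        cube: FeatureCube,
        val_fraction_years: float = 0.2,
        config: TrainConfig | None = None,
        dtype=np.float64,
    ) -> "YieldLSTM":
        """Split the most recent fraction of training years off as validation."""
        years = np.unique(cube.years)
        n_val = max(1, int(round(val_fraction_years * len(years)))) if len(years) > 1 else 0
        if n_val == 0:
            return cls(cube, config=config, dtype=dtype)
        val_years = set(years[-n_val:].tolist())
        is_val = np.isin(cube.years, list(val_years))
        return cls(cube.subset(~is_val), config=config, val_cube=cube.subset(is_val), dtype=dtype)

    def _standardize_like_train(self, cube: FeatureCube) -> np.ndarray:
        if cube.var_names != self.train_cube.var_names:
            raise ValueError("validation cube channel order differs from training cube")
        z = (cube.values - self.train_cube.norm_mean[:, None, None]) / self.train_cube.norm_sd[
            :, None, None
        ]
        return np.ascontiguousarray(np.transpose(z, (2, 1, 0))).astype(self.dtype)

    def fit(self, seed: int = 0, config: TrainConfig | None = None) -> "YieldLSTMResults":
        cfg = config or self.config
        params, history = lstm.train(
            self._X,
            self._y,
            cfg,
            seed=seed,
            X_val=self._Xv,
            y_val=self._yv,
            channel_names=tuple(self.train_cube.var_names),
            dtype=self.dtype,
        )
        return YieldLSTMResults(self, params, history, cfg, seed)

    def search(
        self,
        space: SearchSpace | None = None,
        budget: int = 8,
        seed: int = 0,
        epochs: int = 6,
        patience: int | None = 3,
    ) -> tuple[TrainConfig, pd.DataFrame]:
        """Random hyperparameter search ranked by validation MSE."""
        if self._Xv is None:
            raise ValueError("hyperparameter search needs a validation cube")
        return lstm.random_search(
            self._X,
            self._y,
            self._Xv,
            self._yv,
            space or SearchSpace(),
            budget=budget,
            seed=seed,
            epochs=epochs,
            patience=patience,
            dtype=self.dtype,
        )


class YieldLSTMResults:
    """Fitted LSTM: parameters, training history, prediction and persistence."""

    def __init__(self, model: YieldLSTM, params: ModelParams, history: pd.DataFrame,
                 config: TrainConfig, seed: int):
        self.model = model
        self.params = params
        self.history = history
        self.config = config
        self.seed = seed
        # carried for standalone prediction after load()
        self.var_names = list(model.train_cube.var_names) if model is not None else list(
            params.channel_names
        )
        self.norm_mean = model.train_cube.norm_mean if model is not None else None
        self.norm_sd = model.train_cube.norm_sd if model is not None else None

    def predict(self, cube: FeatureCube) -> np.ndarray:
        """De-trended (base-year bu/ac) predictions for every sample of a cube."""
        if cube.var_names != self.var_names:
            raise ValueError("cube channel order does not match the fitted model")
        if cube.n_time != self.params.n_time:
            raise ValueError(
                f"cube has {cube.n_time} days; model was trained on {self.params.n_time}"
            )
        z = (cube.values - self.norm_mean[:, None, None]) / self.norm_sd[:, None, None]
        X = np.ascontiguousarray(np.transpose(z, (2, 1, 0)))
        return lstm.predict(X, self.params)

    @property
    def final_train_mse(self) -> float:
        return float(self.history["train_mse"].iloc[-1])

    @property
    def best_val_mse(self) -> float:
        return float(np.nanmin(self.history["val_mse"]))

    def summary(self) -> str:
        p = self.params
        lines = [
            "Many-to-one LSTM yield model",
            "=" * 34,
            f"layers:            {len(p.layers)} x {p.layers[0].hidden} hidden units",
            f"input channels:    {len(self.var_names)} ({', '.join(self.var_names)})",
            f"sequence length:   {p.n_time} days",
            f"trainable params:  {p.n_params}",
            f"optimizer:         {self.config.optimizer} (lr={self.config.learning_rate:g})",
            f"dropout:           {self.config.dropout:g}",
            f"epochs run:        {len(self.history)}",
            f"final train MSE:   {self.final_train_mse:.3f} (bu/ac)^2",
        ]
        if np.isfinite(self.history["val_mse"]).any():
            lines.append(f"best val MSE:      {self.best_val_mse:.3f} (bu/ac)^2")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Directory of array file + JSON metadata (shapes, channels, scaling)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, l in enumerate(self.params.layers):
            arrays[f"W{i}"], arrays[f"U{i}"], arrays[f"b{i}"] = l.W, l.U, l.b
        arrays["v"], arrays["b_out"] = self.params.v, self.params.b_out
        arrays["norm_mean"], arrays["norm_sd"] = self.norm_mean, self.norm_sd
        np.savez(path / "params.npz", **arrays)
        meta = {
            "n_layers": len(self.params.layers),
            "dropout": self.params.dropout,
            "n_time": self.params.n_time,
            "var_names": self.var_names,
            "target_mean": self.params.target_mean,
            "target_sd": self.params.target_sd,
            "config": asdict(self.config),
            "seed": self.seed,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
        self.history.to_csv(path / "history.csv", index=False)

    @classmethod
    def load(cls, path) -> "YieldLSTMResults":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        with np.load(path / "params.npz") as npz:
            arrays = {k: npz[k] for k in npz.files}
        layers = [
            lstm.LSTMLayerParams(arrays[f"W{i}"], arrays[f"U{i}"], arrays[f"b{i}"])
            for i in range(meta["n_layers"])
        ]
        params = ModelParams(
            layers=layers,
            v=arrays["v"],
            b_out=arrays["b_out"],
            dropout=meta["dropout"],
            channel_names=tuple(meta["var_names"]),
            n_time=meta["n_time"],
            target_mean=meta["target_mean"],
            target_sd=meta["target_sd"],
        )
        out = cls.__new__(cls)
        out.model = None
        out.params = params
        out.history = pd.read_csv(path / "history.csv")
        out.config = TrainConfig(**meta["config"])
        out.seed = meta["seed"]
        out.var_names = meta["var_names"]
        out.norm_mean = arrays["norm_mean"]
        out.norm_sd = arrays["norm_sd"]
        return out
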