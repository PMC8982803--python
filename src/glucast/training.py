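"""Optimization loop, early stopping, grid search and multi-seed protocols.

Training minimizes the Gaussian NLL with Adam.  Early stopping monitors a
validation metric (NLL by default, RMSE optionally) and returns the
parameters from the best validation epoch.  Given a seed, data and config,
the trajectory is fully deterministic in single-threaded mode: the seed
drives initialization, batch shuffling and dropout through one generator.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .cgm_data import WindowedDataset
from .model import (
    ModelConfig,
    Params,
    forward,
    init_params,
    nll_and_grads,
    nll_loss,
)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 1024
    max_epochs: int = 10_000
    patience: int = 200          # 20 for grid search, 200 for final runs
    seed: int = 0
    monitor: str = "nll"         # "nll" or "rmse" on the validation split
    min_delta: float = 0.0
    grad_clip: float | None = 100.0  # global-norm clip; guards tiny-sigma spikes

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs, patience must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.monitor not in ("nll", "rmse"):
            raise ValueError("monitor must be 'nll' or 'rmse'")


@dataclass
class TrainResult:
    params: Params
    log: pd.DataFrame            # epoch, train_nll, val_metric
    best_epoch: int
    best_val: float
    config: ModelConfig


class _Adam:
    """Adam with bias correction; state keyed like the parameter dict."""

    def __init__(self, params: Params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _as_xy(data: WindowedDataset | tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, WindowedDataset):
        return data.X, data.y
    X, y = data
    return np.asarray(X, float), np.asarray(y, float)


def _clip_global(grads: Params, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _val_metric(X: np.ndarray, y: np.ndarray, params: Params,
                config: ModelConfig, monitor: str) -> float:
    pred = forward(X, params, config)
    if monitor == "rmse":
        return evaluation.rmse(pred.mu, y)
    return nll_loss(pred, y)


def train(
    model_config: ModelConfig,
    train_data: WindowedDataset | tuple[np.ndarray, np.ndarray],
    val_data: WindowedDataset | tuple[np.ndarray, np.ndarray],
    train_config: TrainConfig,
) -> TrainResult:
    """Fit the model by Adam on the mean NLL with early stopping.

    Stops when the validation metric has not improved for ``patience`` epochs
    (or at ``max_epochs``) and returns the parameters of the best epoch seen.
    """
    Xtr, ytr = _as_xy(train_data)
    Xva, yva = _as_xy(val_data)
    if len(ytr) == 0:
        raise ValueError("empty training set")
    if len(yva) == 0:
        raise ValueError("empty validation set")

    rng = np.random.default_rng(train_config.seed)
    params = init_params(model_config, rng)
    opt = _Adam(params, train_config.learning_rate)

    best_val = np.inf
    best_params = copy.deepcopy(params)
    best_epoch = 0
    wait = 0
    rows = []
    n = len(ytr)
    bs = min(train_config.batch_size, n)

    for epoch in range(1, train_config.max_epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            try:
                loss, grads = nll_and_grads(
                    Xtr[idx], ytr[idx], params, model_config, train=True, rng=rng
                )
            except FloatingPointError as exc:
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (non-finite loss); "
                    "lower the learning rate or enable gradient clipping"
                ) from exc
            if train_config.grad_clip is not None:
                _clip_global(grads, train_config.grad_clip)
            opt.step(params, grads)
            losses.append(loss)
        val = _val_metric(Xva, yva, params, model_config, train_config.monitor)
        rows.append({"epoch": epoch, "train_nll": float(np.mean(losses)), "val_metric": val})
        if val < best_val - train_config.min_delta:
            best_val = val
            best_params = copy.deepcopy(params)
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= train_config.patience:
                break
    return TrainResult(
        params=best_params,
        log=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val=float(best_val),
        config=model_config,
    )


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid: LSTM size x history length, several seeds per cell."""

    lstm_units_candidates: tuple[int, ...] = (8, 32, 128, 256, 512)
    history_minutes_candidates: tuple[int, ...] = (30, 60, 120, 180)
    n_seeds: int = 30
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.lstm_units_candidates or not self.history_minutes_candidates:
            raise ValueError("candidate sets must be non-empty")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


def grid_search(
    grid: GridSpec,
    data_for_history: Callable[[int], tuple],
    model_config_factory: Callable[[int, int], ModelConfig],
    train_config: TrainConfig,
) -> pd.DataFrame:
    """Mean/std of selection-set RMSE per (units, history) cell over seeds.

    ``data_for_history(history_minutes)`` must return (train, val, selection)
    window sets built for that history; ``model_config_factory(units,
    history_minutes)`` builds the architecture.  Selection among the rows is a
    documented human step; the full table is returned.  A failed cell training
    is recorded (``n_failed``), not fatal.  Seeds are disjoint per cell and
    listed in the output.
    """
    rows = []
    cell = 0
    for units in grid.lstm_units_candidates:
        for hist in grid.history_minutes_candidates:
            tr, va, sel = data_for_history(hist)
            seeds = [int((grid.base_seed + cell * grid.n_seeds + s) % 2**31)
                     for s in range(grid.n_seeds)]
            cell += 1
            rmses, failures = [], 0
            for seed in seeds:
                cfg = TrainConfig(**{**train_config.__dict__, "seed": seed})
                try:
                    res = train(model_config_factory(units, hist), tr, va, cfg)
                    Xs, ys = _as_xy(sel)
                    pred = forward(Xs, res.params, res.config)
                    rmses.append(evaluation.rmse(pred.mu, ys))
                except (RuntimeError, ValueError):
                    failures += 1
            mean, std = evaluation.mean_and_std(rmses) if rmses else (np.nan, np.nan)
            rows.append({
                "lstm_units": units,
                "history_minutes": hist,
                "seeds": seeds,
                "mean_rmse": mean,
                "std_rmse": std,
                "n_failed": failures,
            })
    return pd.DataFrame(rows)


def multi_seed_run(
    n_seeds: int,
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_data,
    val_data,
    test_data,
) -> tuple[pd.DataFrame, dict]:
    """Train ``n_seeds`` models differing only in seed; report per-seed test
    RMSE with mean and population standard deviation."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    Xte, yte = _as_xy(test_data)
    rows = []
    for s in range(n_seeds):
        seed = int((train_config.seed + s) % 2**31)
        cfg = TrainConfig(**{**train_config.__dict__, "seed": seed})
        res = train(model_config, train_data, val_data, cfg)
        pred = forward(Xte, res.params, res.config)
        rows.append({
            "seed": seed,
            "rmse": evaluation.rmse(pred.mu, yte),
            "mean_sigma": float(np.mean(pred.sigma)),
            "best_epoch": res.best_epoch,
        })
    df = pd.DataFrame(rows)
    mean, std = evaluation.mean_and_std(df["rmse"].to_numpy())
    return df, {"rmse_mean": mean, "rmse_std": std, "n_seeds": n_seeds}


def load_train_config(path: str | Path, **overrides) -> TrainConfig:
    """Read a TrainConfig from a YAML (or JSON) key-value file.

    Unknown keys raise; keyword overrides win over file values.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of TrainConfig fields")
    known = set(TrainConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown TrainConfig fields {sorted(unknown)}")
    data.update(overrides)
    return TrainConfig(**data)


def fast_model_config(history_len: int, horizon_steps: int) -> ModelConfig:
    """Desk-scale architecture: 32 LSTM units, 64/32 dense, no dropout."""
    return ModelConfig(
        history_len=history_len,
        horizon_steps=horizon_steps,
        lstm_units=32,
        dense_sizes=(64, 32),
        dropout_rates=(0.0, 0.0),
    )


def fast_train_config(seed: int = 0, **overrides) -> TrainConfig:
    """Desk-scale optimization: small batches, few hundred epochs."""
    kwargs = dict(
        learning_rate=3e-3,
        batch_size=256,
        max_epochs=300,
        patience=30,
        seed=seed,
    )
    kwargs.update(overrides)
    return TrainConfig(**kwargs)
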