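"""LSTM network with a Gaussian output head, trained by negative log-likelihood.

The network reads a window of scaled glucose history one scalar per step
through an LSTM, feeds the final cell output through two rectified-linear
dense layers (with dropout during training), and emits the parameters of a
univariate Gaussian predictive distribution: a linear head for the mean mu and
an exponential head for the standard deviation sigma, so sigma > 0 by
construction.

Everything here is plain NumPy.  The forward pass caches activations so the
analytic backward pass (backpropagation through time) can produce exact
gradients of the mean NLL; correctness is pinned by finite-difference checks
in the test suite.  Internally the sigma head predicts log(sigma), clamped to
[-10, 10] before exponentiation, which keeps the loss finite for any
parameters.

Gate layout in the packed LSTM matrices is ``[input, forget, output, update]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

LOG_SIGMA_CLAMP = 10.0
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``lstm_units`` is the LSTM state size; ``dense_sizes``/``dropout_rates``
    describe the fully connected stack after the recurrent part (defaults: 512
    and 256 units with 20% and 30% dropout); ``history_len`` is the number of
    input samples h and ``horizon_steps`` the forecast lead d in nominal steps.
    """

    history_len: int
    horizon_steps: int
    lstm_units: int = 256
    dense_sizes: tuple[int, ...] = (512, 256)
    dropout_rates: tuple[float, ...] = (0.20, 0.30)
    forget_bias: float = 1.0

    def __post_init__(self) -> None:
        if self.history_len < 1 or self.horizon_steps < 1:
            raise ValueError("history_len and horizon_steps must be positive")
        if self.lstm_units < 1:
            raise ValueError("lstm_units must be positive")
        if len(self.dense_sizes) != len(self.dropout_rates):
            raise ValueError("dense_sizes and dropout_rates must have equal length")
        if any(not (0.0 <= p < 1.0) for p in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")


@dataclass(frozen=True)
class GaussianPrediction:
    """Predictive distribution(s): mean and standard deviation, sigma > 0."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, float))
        sigma = np.atleast_1d(np.asarray(self.sigma, float))
        if mu.shape != sigma.shape:
            raise ValueError("mu and sigma must have matching shapes")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class LSTMState:
    """Recurrent state: internal memory c and cell output h."""

    c: np.ndarray
    h: np.ndarray


Params = dict[str, np.ndarray]


def init_params(config: ModelConfig, rng: np.random.Generator) -> Params:
    """Initialize all weights.

    Input and dense weights use Glorot-uniform; recurrent weights are
    block-orthogonal per gate; biases are zero except the forget gate, which
    starts at ``config.forget_bias`` (default 1) so early training does not
    flush the cell memory.
    """
    H = config.lstm_units

    def glorot(fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    def orthogonal(n: int) -> np.ndarray:
        q, r = np.linalg.qr(rng.standard_normal((n, n)))
        return q * np.sign(np.diag(r))

    params: Params = {
        "W": glorot(1 + H, H, (1, 4 * H)),
        "U": np.concatenate([orthogonal(H) for _ in range(4)], axis=1),
        "b": np.zeros(4 * H),
    }
    params["b"][H : 2 * H] = config.forget_bias  # forget gate block
    prev = H
    for i, size in enumerate(config.dense_sizes):
        params[f"W_d{i}"] = glorot(prev, size, (prev, size))
        params[f"b_d{i}"] = np.zeros(size)
        prev = size
    params["w_mu"] = glorot(prev, 1, (prev,))
    params["b_mu"] = np.zeros(1)
    params["w_ls"] = glorot(prev, 1, (prev,))
    params["b_ls"] = np.zeros(1)
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_step(x_t: np.ndarray | float, state: LSTMState, params: Params) -> LSTMState:
    """One LSTM transition.

    Gates: i, f, o = sigmoid(W x + U h + b); candidate u = tanh(...);
    c_t = i * u + f * c_{t-1}; h_t = o * tanh(c_t).
    Accepts a scalar input with (H,) state or a (B, 1) batch with (B, H) state.
    """
    x = np.atleast_2d(np.asarray(x_t, float))
    if x.shape[-1] != 1:
        x = x.reshape(-1, 1)
    h_prev = np.atleast_2d(state.h)
    c_prev = np.atleast_2d(state.c)
    H = params["U"].shape[0]
    if h_prev.shape[-1] != H or c_prev.shape[-1] != H:
        raise ValueError(
            f"state size {h_prev.shape[-1]} does not match lstm_units {H}"
        )
    z = x @ params["W"] + h_prev @ params["U"] + params["b"]
    i = _sigmoid(z[:, :H])
    f = _sigmoid(z[:, H : 2 * H])
    o = _sigmoid(z[:, 2 * H : 3 * H])
    u = np.tanh(z[:, 3 * H :])
    c = i * u + f * c_prev
    h = o * np.tanh(c)
    if np.ndim(state.h) == 1:
        return LSTMState(c=c[0], h=h[0])
    return LSTMState(c=c, h=h)


def zero_state(config: ModelConfig, batch: int | None = None) -> LSTMState:
    shape = (config.lstm_units,) if batch is None else (batch, config.lstm_units)
    return LSTMState(c=np.zeros(shape), h=np.zeros(shape))


def _forward_cached(
    X: np.ndarray,
    params: Params,
    config: ModelConfig,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run the network over a batch, keeping activations for backprop."""
    X = np.atleast_2d(np.asarray(X, float))
    B, T = X.shape
    if T != config.history_len:
        raise ValueError(f"history length {T} does not match config ({config.history_len})")
    H = config.lstm_units
    cache: dict = {"steps": [], "X": X}
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        x_t = X[:, t : t + 1]
        z = x_t @ params["W"] + h @ params["U"] + params["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        o = _sigmoid(z[:, 2 * H : 3 * H])
        u = np.tanh(z[:, 3 * H :])
        c_new = i * u + f * c
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache["steps"].append((x_t, h, c, i, f, o, u, tanh_c))
        h, c = h_new, c_new
    cache["h_last"] = h

    a = h
    dense_cache = []
    for li in range(len(config.dense_sizes)):
        z_li = a @ params[f"W_d{li}"] + params[f"b_d{li}"]
        act = np.maximum(z_li, 0.0)
        if train and config.dropout_rates[li] > 0.0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = 1.0 - config.dropout_rates[li]
            mask = (rng.random(act.shape) < keep) / keep
        else:
            mask = None
        out = act if mask is None else act * mask
        dense_cache.append((a, z_li, mask, out))
        a = out
    cache["dense"] = dense_cache
    cache["h_fc"] = a

    mu = a @ params["w_mu"] + params["b_mu"][0]
    ls_pre = a @ params["w_ls"] + params["b_ls"][0]
    ls = np.clip(ls_pre, -LOG_SIGMA_CLAMP, LOG_SIGMA_CLAMP)
    cache["ls_pre"] = ls_pre
    cache["ls"] = ls
    sigma = np.exp(ls)
    return mu, sigma, cache


def forward(X: np.ndarray, params: Params, config: ModelConfig) -> GaussianPrediction:
    """Inference-mode forward pass: dropout off, deterministic in (X, params)."""
    one = np.ndim(X) == 1
    mu, sigma, _ = _forward_cached(X, params, config, train=False)
    if one:
        return GaussianPrediction(mu=mu[:1], sigma=sigma[:1])
    return GaussianPrediction(mu=mu, sigma=sigma)


def nll_loss(
    predictions: GaussianPrediction | np.ndarray,
    targets: np.ndarray,
    sigma: np.ndarray | None = None,
) -> float:
    """Mean Gaussian negative log-likelihood.

    ``(1/k) * sum_i -log N(y_i | mu_i, sigma_i^2)`` with the natural log.
    Accepts either a :class:`GaussianPrediction` or separate (mu, sigma).
    """
    if isinstance(predictions, GaussianPrediction):
        mu, sig = predictions.mu, predictions.sigma
    else:
        if sigma is None:
            raise ValueError("sigma required when predictions is a plain mu array")
        mu, sig = np.atleast_1d(np.asarray(predictions, float)), np.atleast_1d(np.asarray(sigma, float))
    y = np.atleast_1d(np.asarray(targets, float))
    if len(y) == 0:
        raise ValueError("empty batch")
    if mu.shape != y.shape or sig.shape != y.shape:
        raise ValueError("predictions and targets must have matching lengths")
    if np.any(sig <= 0):
        raise ValueError("sigma must be strictly positive")
    z = (y - mu) / sig
    return float(np.mean(_HALF_LOG_2PI + np.log(sig) + 0.5 * z * z))


def nll_and_grads(
    X: np.ndarray,
    y: np.ndarray,
    params: Params,
    config: ModelConfig,
    train: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, Params]:
    """Mean NLL over a batch and its exact gradient w.r.t. every parameter."""
    y = np.asarray(y, float)
    mu, sigma, cache = _forward_cached(X, params, config, train=train, rng=rng)
    B = len(y)
    z = (y - mu) / sigma
    loss = float(np.mean(_HALF_LOG_2PI + cache["ls"] + 0.5 * z * z))
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite NLL loss")

    grads: Params = {k: np.zeros_like(v) for k, v in params.items()}
    dmu = (mu - y) / (sigma**2) / B
    dls = (1.0 - z * z) / B
    # clamp is flat outside the interval
    inside = np.abs(cache["ls_pre"]) < LOG_SIGMA_CLAMP
    dls = np.where(inside, dls, 0.0)

    a = cache["h_fc"]
    grads["w_mu"] = a.T @ dmu
    grads["b_mu"] = np.array([dmu.sum()])
    grads["w_ls"] = a.T @ dls
    grads["b_ls"] = np.array([dls.sum()])
    da = np.outer(dmu, params["w_mu"]) + np.outer(dls, params["w_ls"])

    for li in range(len(config.dense_sizes) - 1, -1, -1):
        a_in, z_li, mask, _out = cache["dense"][li]
        if mask is not None:
            da = da * mask
        dz = da * (z_li > 0)
        grads[f"W_d{li}"] = a_in.T @ dz
        grads[f"b_d{li}"] = dz.sum(axis=0)
        da = dz @ params[f"W_d{li}"].T

    H = config.lstm_units
    dh = da
    dc = np.zeros_like(dh)
    gW, gU, gb = grads["W"], grads["U"], grads["b"]
    for t in range(config.history_len - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, o, u, tanh_c = cache["steps"][t]
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
        di = dc * u
        du = dc * i
        df = dc * c_prev
        dc = dc * f
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), du * (1 - u * u)],
            axis=1,
        )
        gW += x_t.T @ dz
        gU += h_prev.T @ dz
        gb += dz.sum(axis=0)
        dh = dz @ params["U"].T
    return loss, grads


def save_model(
    path: str | Path,
    params: Params,
    config: ModelConfig,
    meta: Mapping | None = None,
) -> Path:
    """Save parameters as an ``.npz`` archive plus a JSON config sidecar.

    The sidecar records the architecture, horizon and any extra metadata
    (e.g. the value scaling), so a saved model is self-describing.
    """
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **params)
    sidecar = {"config": asdict(config), "meta": dict(meta or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_model(path: str | Path) -> tuple[Params, ModelConfig, dict]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as npz:
        params = {k: npz[k].copy() for k in npz.files}
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = dict(sidecar["config"])
    cfg_dict["dense_sizes"] = tuple(cfg_dict["dense_sizes"])
    cfg_dict["dropout_rates"] = tuple(cfg_dict["dropout_rates"])
    return params, ModelConfig(**cfg_dict), sidecar.get("meta", {})
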