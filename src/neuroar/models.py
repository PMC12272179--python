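"""The auto-regressive model zoo and its training machinery.

Five families predict the next time point of all P parcels from a window of
the k previous time points:

* ``linear_uni`` — one linear filter per parcel over its own past (a bank of
  independent univariate AR models);
* ``linear_multi`` — one linear map from the full flattened window to all
  parcels (the classical VAR form);
* ``mlp_uni`` / ``mlp_multi`` — the same two wirings with hidden layers and
  ReLU activations;
* ``chebnet`` — a Chebyshev spectral graph-convolution network: the k window
  steps enter as k input channels per parcel node, and each layer mixes
  channels through polynomials of the scaled graph Laplacian,
  T_0(L~)x = x, T_1(L~)x = L~x, T_j = 2 L~ T_{j-1} - T_{j-2},
  so that information propagates at most K-1 hops per layer. With
  ``nonlinear=False`` the ReLUs are dropped and the whole network collapses
  to a single linear operator built from powers of L~ (the "linear Chebnet").

Training minimizes mean squared prediction error with Adam (no weight
decay); gradients are computed by analytic backpropagation in numpy.
Validation loss is tracked per epoch and the parameters of the best
validation epoch are the ones returned.
"""

from __future__ import annotations

import copy
import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ParcelTimeSeries
from .errors import (ContractError, DivergenceError, InvalidConfigError,
                     NoViableConfigError)
from .graphs import SpectralOperator
from .preprocess import WindowSet, make_windows

__all__ = [
    "ModelConfig",
    "ARModel",
    "build_model",
    "forward",
    "chebyshev_basis_apply",
    "chebnet_forward",
    "count_parameters",
    "fit",
    "grid_search",
    "predict_iterated",
    "fit_direct_multilag",
    "IteratedPredictions",
]

FAMILIES = ("linear_uni", "linear_multi", "mlp_uni", "mlp_multi", "chebnet")


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    family: str
    k: int = 1
    hidden_sizes: tuple = ()
    cheb_order: int = 1          # K, the Chebyshev polynomial order
    nonlinear: bool = True
    bias: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidConfigError(f"unknown family {self.family!r}")
        if self.k < 1:
            raise InvalidConfigError("k must be >= 1")
        if self.family == "chebnet" and self.cheb_order < 1:
            raise InvalidConfigError("cheb_order must be >= 1 for chebnet")
        if self.family.startswith("linear") and self.hidden_sizes:
            raise InvalidConfigError("hidden_sizes must be empty for linear families")
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))

    @property
    def n_layers(self) -> int:
        return len(self.hidden_sizes) + 1


@dataclasses.dataclass
class ARModel:
    config: ModelConfig
    n_parcels: int
    params: dict
    spectral_op: Optional[SpectralOperator] = None
    training_history: list = dataclasses.field(default_factory=list)


def _init_uniform(rng, shape, fan_in):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def build_model(config: ModelConfig, n_parcels: int,
                spectral_op: Optional[SpectralOperator] = None) -> ARModel:
    """Initialize a model of the requested family (uniform fan-in scaling, seeded)."""
    P, k = n_parcels, config.k
    rng = np.random.default_rng(config.seed)
    params: dict = {}
    fam = config.family
    if fam == "chebnet" and spectral_op is None:
        raise ContractError("chebnet requires a SpectralOperator")

    if fam == "linear_uni":
        params["W0"] = _init_uniform(rng, (P, k), k)
        if config.bias:
            params["b0"] = np.zeros(P)
    elif fam == "linear_multi":
        params["W0"] = _init_uniform(rng, (k * P, P), k * P)
        if config.bias:
            params["b0"] = np.zeros(P)
    elif fam == "mlp_uni":
        dims = [k, *config.hidden_sizes, 1]
        for i, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            params[f"W{i}"] = _init_uniform(rng, (P, din, dout), din)
            if config.bias:
                params[f"b{i}"] = np.zeros((P, dout))
    elif fam == "mlp_multi":
        dims = [k * P, *config.hidden_sizes, P]
        for i, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            params[f"W{i}"] = _init_uniform(rng, (din, dout), din)
            if config.bias:
                params[f"b{i}"] = np.zeros(dout)
    elif fam == "chebnet":
        K = config.cheb_order
        chans = [k, *config.hidden_sizes, 1]
        for i, (cin, cout) in enumerate(zip(chans[:-1], chans[1:])):
            params[f"theta{i}"] = _init_uniform(rng, (K, cin, cout), K * cin)
            if config.bias:
                params[f"b{i}"] = np.zeros(cout)
    return ARModel(config=config, n_parcels=P, params=params, spectral_op=spectral_op)


def chebyshev_basis_apply(spectral_op: SpectralOperator, x: np.ndarray, K: int) -> np.ndarray:
    """Stack [T_0(L~)x, ..., T_{K-1}(L~)x] via the three-term recurrence.

    ``x`` has the node axis second-to-last (``(P, C)`` or ``(N, P, C)``); no
    eigendecomposition is performed.
    """
    if K < 1:
        raise InvalidConfigError("K must be >= 1")
    Lt = spectral_op.scaled_laplacian
    terms = [np.asarray(x, dtype=float)]
    if K > 1:
        terms.append(np.einsum("pq,...qc->...pc", Lt, terms[0]))
    for _ in range(2, K):
        terms.append(2.0 * np.einsum("pq,...qc->...pc", Lt, terms[-1]) - terms[-2])
    return np.stack(terms)


def _check_windows(model: ARModel, windows: np.ndarray) -> np.ndarray:
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3 or windows.shape[1] != model.config.k \
            or windows.shape[2] != model.n_parcels:
        raise ContractError(
            f"windows shape {windows.shape} does not match (N, k={model.config.k}, "
            f"P={model.n_parcels})")
    return windows


def _forward(model: ARModel, windows: np.ndarray, need_cache: bool = False):
    """Forward pass; optionally returns the activation cache for backprop."""
    cfg, p = model.config, model.params
    fam = cfg.family
    relu_hidden = cfg.nonlinear
    cache: dict = {}

    if fam == "linear_uni":
        pred = np.einsum("nkp,pk->np", windows, p["W0"])
        if cfg.bias:
            pred = pred + p["b0"]
    elif fam == "linear_multi":
        x = windows.reshape(windows.shape[0], -1)
        pred = x @ p["W0"]
        if cfg.bias:
            pred = pred + p["b0"]
        cache["x"] = x
    elif fam == "mlp_uni":
        a = np.ascontiguousarray(windows.transpose(0, 2, 1))  # (N, P, k)
        acts, zs = [a], []
        for i in range(cfg.n_layers):
            z = np.einsum("npi,pio->npo", a, p[f"W{i}"])
            if cfg.bias:
                z = z + p[f"b{i}"]
            zs.append(z)
            a = np.maximum(z, 0.0) if (relu_hidden and i < cfg.n_layers - 1) else z
            acts.append(a)
        pred = a[..., 0]
        cache.update(acts=acts, zs=zs)
    elif fam == "mlp_multi":
        a = windows.reshape(windows.shape[0], -1)
        acts, zs = [a], []
        for i in range(cfg.n_layers):
            z = a @ p[f"W{i}"]
            if cfg.bias:
                z = z + p[f"b{i}"]
            zs.append(z)
            a = np.maximum(z, 0.0) if (relu_hidden and i < cfg.n_layers - 1) else z
            acts.append(a)
        pred = a
        cache.update(acts=acts, zs=zs)
    elif fam == "chebnet":
        a = np.ascontiguousarray(windows.transpose(0, 2, 1))  # (N, P, C0=k)
        K = cfg.cheb_order
        acts, zs, bases = [a], [], []
        for i in range(cfg.n_layers):
            basis = chebyshev_basis_apply(model.spectral_op, a, K)  # (K, N, P, Cin)
            z = np.einsum("jnpc,jco->npo", basis, p[f"theta{i}"])
            if cfg.bias:
                z = z + p[f"b{i}"]
            bases.append(basis if need_cache else None)
            zs.append(z)
            a = np.maximum(z, 0.0) if (relu_hidden and i < cfg.n_layers - 1) else z
            acts.append(a)
        pred = a[..., 0]
        cache.update(acts=acts, zs=zs, bases=bases)
    else:  # pragma: no cover
        raise ContractError(fam)
    return (pred, cache) if need_cache else pred


def forward(model: ARModel, windows: np.ndarray) -> np.ndarray:
    """Predict the next time point (N x P) from N windows of shape k x P."""
    return _forward(model, _check_windows(model, windows))


def chebnet_forward(model: ARModel, windows: np.ndarray) -> np.ndarray:
    """Chebnet-specific forward (identical to :func:`forward`, with contract checks)."""
    if model.config.family != "chebnet":
        raise ContractError("chebnet_forward requires a chebnet model")
    if model.spectral_op is None:
        raise ContractError("chebnet model is missing its SpectralOperator")
    return forward(model, windows)


def _backward(model: ARModel, windows: np.ndarray, cache: dict, g: np.ndarray) -> dict:
    """Gradients of the loss w.r.t. every parameter, given g = dLoss/dPred."""
    cfg, p = model.config, model.params
    fam = cfg.family
    grads: dict = {}
    if fam == "linear_uni":
        grads["W0"] = np.einsum("np,nkp->pk", g, windows)
        if cfg.bias:
            grads["b0"] = g.sum(axis=0)
    elif fam == "linear_multi":
        grads["W0"] = cache["x"].T @ g
        if cfg.bias:
            grads["b0"] = g.sum(axis=0)
    elif fam in ("mlp_uni", "mlp_multi", "chebnet"):
        acts, zs = cache["acts"], cache["zs"]
        gz = g[..., None] if fam in ("mlp_uni", "chebnet") else g
        for i in range(cfg.n_layers - 1, -1, -1):
            if i < cfg.n_layers - 1 and cfg.nonlinear:
                gz = gz * (zs[i] > 0)
            a_in = acts[i]
            if fam == "mlp_uni":
                grads[f"W{i}"] = np.einsum("npi,npo->pio", a_in, gz)
                if cfg.bias:
                    grads[f"b{i}"] = gz.sum(axis=0)
                if i > 0:
                    gz = np.einsum("npo,pio->npi", gz, p[f"W{i}"])
            elif fam == "mlp_multi":
                grads[f"W{i}"] = a_in.T @ gz
                if cfg.bias:
                    grads[f"b{i}"] = gz.sum(axis=0)
                if i > 0:
                    gz = gz @ p[f"W{i}"].T
            else:  # chebnet
                basis = cache["bases"][i]  # (K, N, P, Cin)
                grads[f"theta{i}"] = np.einsum("jnpc,npo->jco", basis, gz)
                if cfg.bias:
                    grads[f"b{i}"] = gz.sum(axis=(0, 1))
                if i > 0:
                    # adjoint: T_j(L~) is symmetric, so backprop re-applies it
                    theta = p[f"theta{i}"]
                    ga = np.zeros_like(a_in)
                    for j in range(cfg.cheb_order):
                        u = np.einsum("npo,co->npc", gz, theta[j])
                        ga += chebyshev_basis_apply(model.spectral_op, u, j + 1)[-1]
                    gz = ga
    return grads


def count_parameters(model: ARModel) -> int:
    """Total number of trainable scalars, biases included."""
    return int(sum(v.size for v in model.params.values()))


def _mse_and_grad(model, windows, targets):
    pred, cache = _forward(model, windows, need_cache=True)
    resid = pred - targets
    loss = float(np.mean(resid ** 2))
    g = 2.0 * resid / resid.size
    return loss, _backward(model, windows, cache, g)


def _full_loss(model, windows, targets, chunk=8192):
    total, n = 0.0, 0
    for start in range(0, windows.shape[0], chunk):
        pred = _forward(model, windows[start:start + chunk])
        resid = pred - targets[start:start + chunk]
        total += float((resid ** 2).sum())
        n += resid.size
    return total / n


def fit(model: ARModel, train: WindowSet, val: Optional[WindowSet] = None, *,
        epochs: int = 50, batch_size: int = 128, learning_rate: float = 1e-2,
        seed: int = 0) -> ARModel:
    """Train with Adam on the mean-squared prediction error (no weight decay).

    Mini-batch order is reshuffled each epoch from ``seed``; per-epoch train
    and validation losses are recorded and the parameters from the epoch with
    the lowest validation loss (train loss when no validation set is given)
    are restored before returning. Bitwise deterministic for fixed inputs.
    """
    if train.n_samples == 0:
        raise InvalidConfigError("empty training WindowSet")
    rng = np.random.default_rng(seed)
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_loss, best_params = np.inf, None
    model.training_history = []

    for epoch in range(epochs):
        perm = rng.permutation(train.n_samples)
        for start in range(0, train.n_samples, batch_size):
            idx = perm[start:start + batch_size]
            loss, grads = _mse_and_grad(model, train.inputs[idx], train.targets[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch, learning_rate)
            step += 1
            for name, grad in grads.items():
                m_state[name] = beta1 * m_state[name] + (1 - beta1) * grad
                v_state[name] = beta2 * v_state[name] + (1 - beta2) * grad ** 2
                m_hat = m_state[name] / (1 - beta1 ** step)
                v_hat = v_state[name] / (1 - beta2 ** step)
                model.params[name] = model.params[name] - learning_rate * m_hat / (
                    np.sqrt(v_hat) + eps)
        train_loss = _full_loss(model, train.inputs, train.targets)
        val_loss = (_full_loss(model, val.inputs, val.targets)
                    if val is not None and val.n_samples else None)
        if not np.isfinite(train_loss) or (val_loss is not None and not np.isfinite(val_loss)):
            raise DivergenceError(epoch, learning_rate)
        model.training_history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        monitor = val_loss if val_loss is not None else train_loss
        if monitor < best_loss:
            best_loss = monitor
            best_params = copy.deepcopy(model.params)
    if best_params is not None:
        model.params = best_params
    return model


@dataclasses.dataclass
class IteratedPredictions:
    """Aligned multi-lag predictions of one run from a lag-1 model.

    ``predictions[l-1][i]`` is the lag-l prediction for target time index
    ``i + k - 1 + l`` of the source series.
    """

    predictions: np.ndarray  # (l_max, T-k, P)
    k: int
    l_max: int
    series: ParcelTimeSeries

    def aligned(self, lag: int):
        """(target time indices, predictions, true values) at one lag."""
        if not 1 <= lag <= self.l_max:
            raise ContractError(f"lag {lag} outside 1..{self.l_max}")
        T = self.series.n_timepoints
        n = T - self.k - lag + 1
        targets_idx = np.arange(self.k - 1 + lag, T)
        return targets_idx, self.predictions[lag - 1][:n], self.series.data[self.k - 1 + lag:]

    def predicted_series(self, lag: int) -> np.ndarray:
        """The lag-l predicted signal as a (T', P) matrix aligned to true time."""
        return self.aligned(lag)[1]


def predict_iterated(model: ARModel, series: ParcelTimeSeries, l_max: int) -> IteratedPredictions:
    """Iterated single-step prediction at lags 1..l_max.

    Lag-1 predictions use the true history; lag-j predictions slide the
    window forward, substituting the j-1 previously predicted values for the
    unavailable true ones.
    """
    k = model.config.k
    T = series.n_timepoints
    if T < k + l_max:
        raise ContractError(f"series length {T} < k + l_max = {k + l_max}")
    sw = np.lib.stride_tricks.sliding_window_view(series.data, k, axis=0)
    windows = np.ascontiguousarray(sw[:T - k].transpose(0, 2, 1))  # (T-k, k, P)
    preds = np.empty((l_max, T - k, model.n_parcels))
    for j in range(l_max):
        preds[j] = forward(model, windows)
        if j < l_max - 1:
            windows = np.concatenate([windows[:, 1:, :], preds[j][:, None, :]], axis=1)
    return IteratedPredictions(predictions=preds, k=k, l_max=l_max, series=series)


def _mean_val_r2(model: ARModel, val_runs: Sequence[ParcelTimeSeries], lags) -> float:
    scores = []
    for run in val_runs:
        it = predict_iterated(model, run, max(lags))
        for lag in lags:
            _, pred, truth = it.aligned(lag)
            ss_res = ((truth - pred) ** 2).sum(axis=0)
            ss_tot = ((truth - truth.mean(axis=0)) ** 2).sum(axis=0)
            scores.append(float(np.mean(1.0 - ss_res / ss_tot)))
    return float(np.mean(scores))


def grid_search(grid: Sequence[ModelConfig], data_by_subject: dict, lags: Sequence[int], *,
                spectral_ops: Optional[dict] = None, epochs: int = 30, batch_size: int = 128,
                learning_rate: float = 1e-2, seed: int = 0):
    """Select the configuration with the highest mean validation R².

    ``data_by_subject`` maps subject -> (train runs, val runs); each
    configuration is trained independently per subject and scored by the mean
    validation R² over subjects, parcels and the listed lags. Ties keep the
    first configuration in grid order. Returns ``(best_config, score_table)``.
    """
    if not grid:
        raise InvalidConfigError("empty grid")
    rows = []
    scores = []
    for ci, config in enumerate(grid):
        subject_scores = []
        try:
            for subject, (train_runs, val_runs) in data_by_subject.items():
                spectral_op = None
                if config.family == "chebnet":
                    spectral_op = (spectral_ops or {}).get(subject) \
                        if isinstance(spectral_ops, dict) else spectral_ops
                model = build_model(config, train_runs[0].n_parcels, spectral_op)
                train_ws = make_windows(train_runs, config.k, 1)
                model = fit(model, train_ws, epochs=epochs, batch_size=batch_size,
                            learning_rate=learning_rate, seed=seed)
                subject_scores.append(_mean_val_r2(model, val_runs, lags))
            score = float(np.mean(subject_scores))
        except DivergenceError:
            score = np.nan
        scores.append(score)
        rows.append({"config_index": ci, "family": config.family, "k": config.k,
                     "score": score})
    table = pd.DataFrame(rows)
    if table["score"].isna().all():
        raise NoViableConfigError("every configuration diverged")
    best = int(np.nanargmax(scores))
    return grid[best], table


def fit_direct_multilag(config, windows_by_lag: dict, n_parcels: int, *,
                        spectral_op: Optional[SpectralOperator] = None,
                        **fit_kwargs) -> dict:
    """Train one independent model per prediction lag (direct multi-step mode).

    ``windows_by_lag`` maps lag -> (train WindowSet, val WindowSet or None);
    ``config`` may be a single ModelConfig applied at each lag, or a dict
    lag -> ModelConfig. Reduces exactly to :func:`fit` when only lag 1 is given.
    """
    models = {}
    for lag in sorted(windows_by_lag):
        cfg = config[lag] if isinstance(config, dict) else config
        train_ws, val_ws = windows_by_lag[lag]
        model = build_model(cfg, n_parcels, spectral_op)
        models[lag] = fit(model, train_ws, val_ws, **fit_kwargs)
    return models
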