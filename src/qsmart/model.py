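"""The response model: linear view and pyramid neural networks.

The linear view is the structure-mutation-activity regression

    log IC50 = b0 + sum_i b1i * D_i + sum_j b2j * C_j
             + sum_ik b3ik * D_i * M_k
             + sum b4p * PPI_p + sum b5q * RECx_q
             + sum b6r * PWYx_r + sum b7s * GOx_s + eps,

an affine model over the named features surviving selection. The neural
view replaces the affine map with a fully connected feed-forward network
whose hidden-layer widths follow the geometric pyramid rule on the number
of inputs N: ceil(N^(1/2)) for the single-layer variant,
(ceil(N^(2/3)), ceil(N^(1/3))) for the double-layer variant, and
(N, ceil(N^(1/2))) for the complex-double variant. Hidden activations are
TanH, biases enter the input and hidden layers, weights carry an
absolute-value (L1) penalty, and training uses a deterministic batch
quasi-Newton optimizer (L-BFGS) with early stopping on validation loss
under 10-fold cross-validation.

Hyperparameter tuning escalates through an architecture/iteration
schedule — (single, 200), (single, 300), (double, 200), (double, 300),
(complex_double, 200), (complex_double, 300) — stopping at the first
stage whose mean cross-validated R^2 reaches the 0.8 performance
threshold.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

log = logging.getLogger("qsmart")

VARIANTS = ("single", "double", "complex_double")

_L1_EPS = 1e-8  # smoothing of |w| for quasi-Newton differentiability


def _ceil_root(n: int, num: int, den: int) -> int:
    """Exact ceil(n^(num/den)) by integer search: smallest m with
    m^den >= n^num (floating powers misround perfect powers)."""
    target = n ** num
    m = max(1, math.floor(n ** (num / den)) - 1)
    while m ** den < target:
        m += 1
    return m


def pyramid_sizes(n_inputs: int, variant: str) -> list[int]:
    """Hidden-layer widths by the geometric pyramid rule.

    single -> [ceil(N^(1/2))]; double -> [ceil(N^(2/3)), ceil(N^(1/3))];
    complex_double -> [N, ceil(N^(1/2))].
    """
    if n_inputs < 1:
        raise ValueError("need at least one input node")
    n = n_inputs
    if variant == "single":
        return [_ceil_root(n, 1, 2)]
    if variant == "double":
        return [_ceil_root(n, 2, 3), _ceil_root(n, 1, 3)]
    if variant == "complex_double":
        return [n, _ceil_root(n, 1, 2)]
    raise ValueError(f"unknown architecture variant {variant!r}")


@dataclass(frozen=True)
class NNArchitecture:
    """Fully connected TanH pyramid network description."""
    n_inputs: int
    variant: str

    @property
    def hidden_sizes(self) -> list[int]:
        return pyramid_sizes(self.n_inputs, self.variant)

    @property
    def layer_sizes(self) -> list[int]:
        return [self.n_inputs, *self.hidden_sizes, 1]


def forward(layers: list[tuple[np.ndarray, np.ndarray]],
            x: np.ndarray) -> np.ndarray:
    """Forward pass: TanH hidden layers, linear output, biases throughout.

    ``layers`` is a list of (weights, bias) pairs; weights of layer l have
    shape (fan_in, fan_out).
    """
    a = np.asarray(x, float)
    for w, b in layers[:-1]:
        a = np.tanh(a @ w + b)
    w, b = layers[-1]
    return (a @ w + b).ravel()


def _init_params(arch: NNArchitecture, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    rng = np.random.default_rng(seed)
    sizes = arch.layer_sizes
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        layers.append((rng.normal(0.0, scale, (fan_in, fan_out)),
                       np.zeros(fan_out)))
    return layers


def _pack(layers):
    return np.concatenate([np.concatenate([w.ravel(), b])
                           for w, b in layers])


def _unpack(theta: np.ndarray, sizes: list[int]):
    layers = []
    off = 0
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        w = theta[off:off + fan_in * fan_out].reshape(fan_in, fan_out)
        off += fan_in * fan_out
        b = theta[off:off + fan_out]
        off += fan_out
        layers.append((w, b))
    return layers


def _loss_grad(theta, sizes, x, y, lam):
    """MSE + smoothed-L1 weight penalty, with analytic gradient."""
    layers = _unpack(theta, sizes)
    n = len(y)
    acts = [x]
    a = x
    for w, b in layers[:-1]:
        a = np.tanh(a @ w + b)
        acts.append(a)
    w_out, b_out = layers[-1]
    pred = (a @ w_out + b_out).ravel()
    resid = pred - y
    loss = float(resid @ resid) / n

    grads = [None] * len(layers)
    delta = (2.0 / n) * resid[:, None]  # (n, 1)
    grads[-1] = (acts[-1].T @ delta, delta.sum(axis=0))
    back = delta @ w_out.T
    for li in range(len(layers) - 2, -1, -1):
        w, b = layers[li]
        d = back * (1.0 - acts[li + 1] ** 2)
        grads[li] = (acts[li].T @ d, d.sum(axis=0))
        back = d @ w.T

    # penalty on weights only, biases free
    for li, (w, b) in enumerate(layers):
        smooth = np.sqrt(w * w + _L1_EPS)
        loss += lam * float(smooth.sum())
        gw, gb = grads[li]
        grads[li] = (gw + lam * w / smooth, gb)
    grad = _pack(grads)
    return loss, grad


class _EarlyStop(Exception):
    pass


def _train_once(x, y, arch, lam, iterations, seed,
                x_val=None, y_val=None,
                patience: int = 10, tol: float = 1e-6):
    """One optimizer run; returns (layers, val_loss, converged)."""
    sizes = arch.layer_sizes
    theta0 = _pack(_init_params(arch, seed))
    state = {"best_loss": np.inf, "best_theta": theta0.copy(), "stale": 0}

    def val_loss(theta):
        layers = _unpack(theta, sizes)
        pred = forward(layers, x_val)
        return float(np.mean((pred - y_val) ** 2))

    def callback(theta):
        vl = val_loss(theta)
        if vl < state["best_loss"] - tol:
            state["best_loss"] = vl
            state["best_theta"] = theta.copy()
            state["stale"] = 0
        else:
            state["stale"] += 1
            if state["stale"] >= patience:
                raise StopIteration

    cb = callback if x_val is not None else None
    res = minimize(_loss_grad, theta0, args=(sizes, x, y, lam),
                   method="L-BFGS-B", jac=True, callback=cb,
                   options={"maxiter": iterations})
    stopped_early = x_val is not None and state["stale"] >= patience
    if x_val is not None and np.isfinite(state["best_loss"]):
        theta = (state["best_theta"]
                 if state["best_loss"] <= val_loss(res.x) else res.x)
        vl = min(state["best_loss"], val_loss(res.x))
    else:
        theta = res.x
        vl = np.nan
    converged = bool(res.success) or stopped_early
    return _unpack(theta, sizes), vl, converged


def _r2(pred: np.ndarray, actual: np.ndarray) -> float:
    tss = float(np.sum((actual - actual.mean()) ** 2))
    rss = float(np.sum((actual - pred) ** 2))
    return 1.0 - rss / tss if tss > 0 else np.nan


class PyramidNetRegressor(RegressorMixin, BaseEstimator):
    """Feed-forward TanH regressor with pyramid-rule hidden sizes.

    Parameters
    ----------
    variant : 'single' | 'double' | 'complex_double'
    max_iter : optimizer iteration cap per fit (the schedule's 200/300).
    l1_grid : candidate L1 penalty strengths; the value with the best
        validation loss per fold is used, and the best overall is kept for
        the final refit on all folds.
    cv : number of cross-validation folds (default 10).
    random_state : seed controlling fold assignment and weight init.

    Attributes
    ----------
    cv_r2_ : mean validation R^2 over folds.
    fold_r2_ : per-fold validation R^2.
    fold_converged_ : per-fold convergence flags (non-convergent folds are
        reported, never dropped).
    best_l1_ : penalty strength chosen by validation loss.
    layers_ : fitted weights of the final refit (standardized space).
    """

    def __init__(self, variant: str = "single", max_iter: int = 200,
                 l1_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2),
                 cv: int = 10, random_state: int = 0):
        self.variant = variant
        self.max_iter = max_iter
        self.l1_grid = l1_grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        cols = [str(c) for c in X.columns]
        mat = X.to_numpy(float)
        y = np.asarray(y, float)
        n, p = mat.shape
        arch = NNArchitecture(p, self.variant)

        mu, sd = mat.mean(axis=0), mat.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        ym, ys = y.mean(), y.std() or 1.0
        xs = (mat - mu) / sd
        yn = (y - ym) / ys

        kf = KFold(n_splits=self.cv, shuffle=True,
                   random_state=self.random_state)
        fold_r2, fold_conv, fold_lam = [], [], []
        for fold_i, (tr, va) in enumerate(kf.split(xs)):
            best = (np.inf, None, None, None)
            for lam in self.l1_grid:
                layers, vl, conv = _train_once(
                    xs[tr], yn[tr], arch, lam, self.max_iter,
                    seed=self.random_state * 1009 + fold_i,
                    x_val=xs[va], y_val=yn[va])
                if vl < best[0]:
                    best = (vl, layers, lam, conv)
            vl, layers, lam, conv = best
            pred = forward(layers, xs[va]) * ys + ym
            fold_r2.append(_r2(pred, y[va]))
            fold_conv.append(conv)
            fold_lam.append(lam)
            if not conv:
                log.warning("fold %d did not converge (lam=%g)", fold_i, lam)

        self.fold_r2_ = np.array(fold_r2)
        self.fold_converged_ = np.array(fold_conv)
        self.cv_r2_ = float(np.mean(fold_r2))
        # hyperparameter from the fold with the best validation statistic
        self.best_l1_ = float(fold_lam[int(np.argmax(fold_r2))])
        self.layers_, _, self.converged_ = _train_once(
            xs, yn, arch, self.best_l1_, self.max_iter,
            seed=self.random_state * 1009 + 997)
        self.architecture_ = arch
        self.x_mean_, self.x_scale_ = mu, sd
        self.y_mean_, self.y_scale_ = ym, ys
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "layers_")
        X = pd.DataFrame(X)
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing model feature: {missing[0]}")
        mat = X[list(self.feature_names_in_)].to_numpy(float)
        xs = (mat - self.x_mean_) / self.x_scale_
        return forward(self.layers_, xs) * self.y_scale_ + self.y_mean_


@dataclass
class QsmartModelSpec:
    """Serialized fitted model: linear and/or neural view over named features.

    The linear view predicts exactly b0 + sum(b_f * x_f); the network view
    is the standardized TanH forward pass. Metadata records seed, folds,
    iterations, and config hash.
    """

    feature_names: list[str]
    intercept: float | None = None
    coefficients: dict[str, float] | None = None
    network: dict | None = None  # layers/scalers/variant
    metadata: dict = field(default_factory=dict)

    @property
    def has_linear(self) -> bool:
        return self.coefficients is not None

    def predict(self, rows: pd.DataFrame, view: str = "linear") -> np.ndarray:
        missing = [c for c in self.feature_names if c not in rows.columns]
        if missing:
            raise ValueError(f"missing model feature: {missing[0]}")
        x = rows[self.feature_names].to_numpy(float)
        if view == "linear":
            if not self.has_linear:
                raise ValueError("model has no linear view")
            beta = np.array([self.coefficients[c] for c in self.feature_names])
            return self.intercept + x @ beta
        if view == "network":
            if self.network is None:
                raise ValueError("model has no network view")
            net = self.network
            xs = (x - np.asarray(net["x_mean"])) / np.asarray(net["x_scale"])
            layers = [(np.asarray(w), np.asarray(b))
                      for w, b in net["layers"]]
            return (forward(layers, xs) * net["y_scale"] + net["y_mean"])
        raise ValueError(f"unknown view {view!r}")

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        Path(path).write_text(json.dumps(self.__dict__, default=default,
                                         indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "QsmartModelSpec":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


def fit_linear(X: pd.DataFrame, y: np.ndarray,
               metadata: dict | None = None) -> QsmartModelSpec:
    """OLS refit of the selected features: the explainable linear view."""
    cols = [str(c) for c in X.columns]
    mat = X.to_numpy(float)
    design = np.column_stack([np.ones(len(mat)), mat])
    beta, *_ = np.linalg.lstsq(design, np.asarray(y, float), rcond=None)
    return QsmartModelSpec(
        feature_names=cols, intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(cols, beta[1:])},
        metadata=metadata or {})


def network_spec_from(est: PyramidNetRegressor,
                      base: QsmartModelSpec | None = None,
                      metadata: dict | None = None) -> QsmartModelSpec:
    """Attach a fitted network view to a model spec."""
    spec = base or QsmartModelSpec(
        feature_names=list(est.feature_names_in_), metadata=metadata or {})
    spec.network = {
        "variant": est.variant,
        "hidden_sizes": est.architecture_.hidden_sizes,
        "layers": [(w.tolist(), b.tolist()) for w, b in est.layers_],
        "x_mean": est.x_mean_.tolist(), "x_scale": est.x_scale_.tolist(),
        "y_mean": est.y_mean_, "y_scale": est.y_scale_,
        "cv_r2": est.cv_r2_,
    }
    return spec


def train_network(X: pd.DataFrame, y: np.ndarray, variant: str,
                  iterations: int, seed: int, cv: int = 10,
                  l1_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2),
                  ) -> PyramidNetRegressor:
    """Functional wrapper: train one architecture under cross-validation."""
    est = PyramidNetRegressor(variant=variant, max_iter=iterations,
                              l1_grid=l1_grid, cv=cv, random_state=seed)
    return est.fit(X, y)


def escalation_schedule(
    X: pd.DataFrame, y: np.ndarray, *,
    schedule: tuple[tuple[str, int], ...] = (
        ("single", 200), ("single", 300), ("double", 200), ("double", 300),
        ("complex_double", 200), ("complex_double", 300)),
    threshold: float = 0.8, seed: int = 0, cv: int = 10,
    l1_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2),
) -> tuple[PyramidNetRegressor, pd.DataFrame]:
    """Escalate architecture/iterations until CV R^2 reaches the threshold.

    Returns the stopping-stage model (or the best seen, flagged in the
    trace) and the full schedule trace.
    """
    rows = []
    best = (-np.inf, None)
    for stage, (variant, iters) in enumerate(schedule):
        est = train_network(X, y, variant, iters, seed, cv, l1_grid)
        reached = est.cv_r2_ >= threshold
        rows.append({"stage": stage, "variant": variant,
                     "iterations": iters, "cv_r2": est.cv_r2_,
                     "reached_threshold": reached})
        if est.cv_r2_ > best[0]:
            best = (est.cv_r2_, est)
        if reached:
            break
    trace = pd.DataFrame(rows)
    if not trace["reached_threshold"].any():
        log.warning("no stage reached CV R^2 >= %.2f; returning best seen",
                    threshold)
    return best[1], trace
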