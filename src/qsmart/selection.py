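"""Collinearity screening and sparse feature selection.

Two estimators reduce the assembled design matrix:

* :class:`VifScreener` — greedy stepwise screening under variance-
  inflation-factor control. Features are visited in a priority order
  (for drug features: later fingerprint bits before earlier ones, all
  fingerprints before descriptors) and a candidate is kept only if,
  after adding it, every kept feature still has
  VIF_i = 1 / (1 - R^2_i) <= the threshold (default 5, i.e. R^2_i <= 0.8).

* :class:`LassoBicSelector` — the Lasso regularization path scored by the
  Bayesian information criterion BIC = k * ln(n) - 2 * ln(L), with k the
  number of non-zero coefficients at a path point and L the Gaussian
  likelihood (error variance RSS/n) of the least-squares refit on that
  support. Scoring the refit rather than the shrunken fit removes the
  penalty bias that otherwise drags extra features into the support; the
  path point minimizing BIC defines the selected features.

:class:`EnsembleRankSelector` implements the average-rank alternative:
features are ranked by absolute correlation with the response, a
relief-style nearest-neighbour relevance score, permutation importance
from a plug-in regressor, and Lasso path entry order; the four ranks are
averaged and the top k (k taken from the Lasso-BIC support size) are kept.

Both screeners compose with sklearn pipelines; module-level functions are
thin wrappers over the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import lasso_path
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

_R2_SINGULAR = 1.0 - 1e-10


def _r2_of_regression(target: np.ndarray, predictors: np.ndarray) -> float:
    """R^2 of OLS of ``target`` on ``predictors`` plus an intercept."""
    tss = float(np.sum((target - target.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant feature: VIF undefined")
    x = np.column_stack([np.ones(len(target)), predictors])
    beta, *_ = np.linalg.lstsq(x, target, rcond=None)
    rss = float(np.sum((target - x @ beta) ** 2))
    return max(0.0, 1.0 - rss / tss)


def compute_vif(i: int, X: np.ndarray) -> float:
    """Variance inflation factor of column ``i`` within design ``X``.

    Regresses feature i on the remaining features; returns
    1 / (1 - R^2_i), or +inf when R^2_i = 1 within tolerance. A single
    remaining feature set of size zero gives VIF = 1 by convention.
    """
    X = np.asarray(X, float)
    if X.shape[1] < 2:
        if np.ptp(X[:, i]) == 0:
            raise ValueError("constant feature: VIF undefined")
        return 1.0
    others = np.delete(X, i, axis=1)
    r2 = _r2_of_regression(X[:, i], others)
    if r2 >= _R2_SINGULAR:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_from_r2(r2: float) -> float:
    """The VIF identity 1 / (1 - R^2_i)."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("R^2 must lie in [0, 1)")
    return 1.0 / (1.0 - r2)


class VifScreener(TransformerMixin, BaseEstimator):
    """Greedy stepwise feature screen under VIF control.

    Parameters
    ----------
    threshold : float, default 5.0
        Maximum tolerated VIF for every kept feature.
    priority : list of column names, optional
        Visiting order; defaults to the input column order. Columns absent
        from ``priority`` are appended in input order.

    Attributes
    ----------
    kept_features_ : list of str
        Features surviving the screen, in acceptance order.
    report_ : pandas.DataFrame
        Per candidate: VIF at decision time, the implied R^2, whether it
        was kept, and the step index at which it was visited.
    """

    def __init__(self, threshold: float = 5.0,
                 priority: list[str] | None = None):
        self.threshold = threshold
        self.priority = priority

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        cols = [str(c) for c in X.columns]
        X.columns = cols
        order = [c for c in (self.priority or cols) if c in cols]
        order += [c for c in cols if c not in order]

        kept: list[str] = []
        rows = []
        data = {c: X[c].to_numpy(float) for c in cols}
        for step, cand in enumerate(order):
            col = data[cand]
            entry = {"feature": cand, "step": step, "vif": np.nan,
                     "r2": np.nan, "kept": False}
            if np.ptp(col) == 0:
                entry["kept"] = False  # constant: VIF undefined, flagged
                entry["vif"] = np.nan
                rows.append(entry)
                continue
            trial = kept + [cand]
            mat = np.column_stack([data[c] for c in trial])
            vifs = []
            ok = True
            for j in range(mat.shape[1]):
                try:
                    v = compute_vif(j, mat)
                except ValueError:
                    ok = False
                    v = np.nan
                    break
                vifs.append(v)
                if v > self.threshold:
                    ok = False
                    break
            entry["vif"] = vifs[-1] if vifs else np.nan
            if np.isfinite(entry["vif"]):
                entry["r2"] = 1.0 - 1.0 / entry["vif"]
            if ok:
                kept.append(cand)
                entry["kept"] = True
            rows.append(entry)
        self.kept_features_ = kept
        self.report_ = pd.DataFrame(rows)
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.n_features_in_ = len(cols)
        return self

    def transform(self, X):
        check_is_fitted(self, "kept_features_")
        return pd.DataFrame(X)[self.kept_features_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "kept_features_")
        return np.asarray(self.kept_features_, dtype=object)


@dataclass
class SelectionResult:
    """Outcome of Lasso-BIC selection on one training set."""
    selected: list[str]
    coefficients: dict[str, float]
    intercept: float
    k: int
    n: int
    log_likelihood: float
    bic: float
    bic_trace: pd.DataFrame


def gaussian_log_likelihood(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood with plug-in variance RSS/n."""
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def bic_score(k: int, n: int, log_likelihood: float) -> float:
    """BIC = k * ln(n) - 2 * ln(L)."""
    return k * np.log(n) - 2.0 * log_likelihood


class LassoBicSelector(TransformerMixin, BaseEstimator):
    """Select the Lasso path point minimizing the BIC.

    Columns are standardized to zero mean and unit variance before the
    penalty is applied; reported coefficients are back-transformed to the
    original scale. ``k`` counts non-zero coefficients; the likelihood is
    Gaussian with plug-in variance RSS/n, evaluated on the least-squares
    refit of each path point's support.

    Attributes
    ----------
    support_ : boolean mask of selected columns.
    selected_features_ : selected column names.
    coef_ : back-transformed coefficients (full length).
    intercept_ : intercept on the original scale.
    bic_, k_, n_, log_likelihood_ : scalars of the chosen path point.
    bic_trace_ : per-path-point alpha, k, and BIC.
    entry_order_ : for each column, the path index at which its
        coefficient first became non-zero (inf if never); used by the
        ensemble ranker.
    """

    def __init__(self, n_alphas: int = 100, eps: float = 1e-3):
        self.n_alphas = n_alphas
        self.eps = eps

    def fit(self, X, y):
        X = pd.DataFrame(X)
        cols = [str(c) for c in X.columns]
        y = np.asarray(y, float)
        n = len(y)
        if n < 2 or np.ptp(y) == 0:
            raise ValueError("response has no variance")
        mat = X.to_numpy(float)
        mu, sd = mat.mean(axis=0), mat.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        xs = (mat - mu) / sd_safe
        ym = y.mean()
        yc = y - ym

        alphas, coefs, _ = lasso_path(xs, yc, alphas=self.n_alphas,
                                      eps=self.eps)
        n_points = len(alphas)
        bics = np.empty(n_points)
        ks = np.empty(n_points, dtype=int)
        lls = np.empty(n_points)
        rss_cache: dict[tuple[int, ...], float] = {}
        for t in range(n_points):
            support = tuple(np.nonzero(coefs[:, t])[0])
            if support not in rss_cache:
                if support:
                    sub = xs[:, support]
                    beta_ols, *_ = np.linalg.lstsq(sub, yc, rcond=None)
                    rss_cache[support] = float(
                        np.sum((yc - sub @ beta_ols) ** 2))
                else:
                    rss_cache[support] = float(yc @ yc)
            k = len(support)
            ll = gaussian_log_likelihood(rss_cache[support], n)
            ks[t], lls[t] = k, ll
            bics[t] = bic_score(k, n, ll)
        best = int(np.argmin(bics))
        beta_std = coefs[:, best]
        beta = beta_std / sd_safe
        beta[sd == 0] = 0.0

        self.support_ = beta_std != 0
        self.selected_features_ = [c for c, s in zip(cols, self.support_) if s]
        self.coef_ = beta
        self.intercept_ = float(ym - beta @ mu)
        self.k_ = int(ks[best])
        self.n_ = n
        self.log_likelihood_ = float(lls[best])
        self.bic_ = float(bics[best])
        self.bic_trace_ = pd.DataFrame(
            {"alpha": alphas, "k": ks, "bic": bics})
        entered = np.full(len(cols), np.inf)
        for t in range(n_points):
            for j in np.nonzero(coefs[:, t])[0]:
                if not np.isfinite(entered[j]):
                    entered[j] = t
        self.entry_order_ = entered
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.n_features_in_ = len(cols)
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        return pd.DataFrame(X)[self.selected_features_]

    def result(self) -> SelectionResult:
        check_is_fitted(self, "selected_features_")
        coef_map = {c: float(b) for c, b, s in
                    zip(self.feature_names_in_, self.coef_, self.support_)
                    if s}
        return SelectionResult(
            selected=list(self.selected_features_),
            coefficients=coef_map, intercept=self.intercept_,
            k=self.k_, n=self.n_, log_likelihood=self.log_likelihood_,
            bic=self.bic_, bic_trace=self.bic_trace_)


def _relief_scores(x: np.ndarray, y: np.ndarray, n_neighbors: int = 5,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """RReliefF-style relevance: features whose differences track response
    differences among nearest neighbours score high."""
    rng = rng or np.random.default_rng(0)
    n, p = x.shape
    sd = x.std(axis=0)
    xs = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    y_range = np.ptp(y) or 1.0
    f_range = np.ptp(xs, axis=0)
    f_range[f_range == 0] = 1.0
    n_dy = 0.0
    n_df = np.zeros(p)
    n_dydf = np.zeros(p)
    k = min(n_neighbors, n - 1)
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(xs)
    _, idx = nbrs.kneighbors(xs)
    for i in range(n):
        nn = idx[i][idx[i] != i][:k]
        dy = np.abs(y[i] - y[nn]) / y_range
        df = np.abs(xs[i] - xs[nn]) / f_range
        n_dy += dy.sum()
        n_df += df.sum(axis=0)
        n_dydf += (dy[:, None] * df).sum(axis=0)
    total = n * k
    with np.errstate(invalid="ignore", divide="ignore"):
        w = n_dydf / n_dy - (n_df - n_dydf) / max(total - n_dy, 1e-12)
    return np.nan_to_num(w)


class EnsembleRankSelector(TransformerMixin, BaseEstimator):
    """Average-rank feature selection over four relevance criteria.

    Ranks by (a) absolute Pearson correlation with the response, (b) a
    relief-style nearest-neighbour score, (c) permutation importance from
    a plug-in regressor (default: random forest), and (d) Lasso path entry
    order; averages the four ranks and keeps the top ``k`` features
    (``k`` defaults to the Lasso-BIC support size). Ties break by feature
    name.
    """

    def __init__(self, k: int | None = None, estimator=None,
                 n_neighbors: int = 5, random_state: int = 0):
        self.k = k
        self.estimator = estimator
        self.n_neighbors = n_neighbors
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        cols = [str(c) for c in X.columns]
        mat = X.to_numpy(float)
        y = np.asarray(y, float)
        p = len(cols)
        rng = np.random.default_rng(self.random_state)

        sd = mat.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(np.array([
                np.corrcoef(mat[:, j], y)[0, 1] if sd[j] > 0 else 0.0
                for j in range(p)]))
        corr = np.nan_to_num(corr)
        relief = _relief_scores(mat, y, self.n_neighbors, rng)

        est = self.estimator
        if est is None:
            est = RandomForestRegressor(n_estimators=50,
                                        random_state=self.random_state)
        est.fit(mat, y)
        perm = permutation_importance(est, mat, y, n_repeats=5,
                                      random_state=self.random_state)
        importance = perm.importances_mean

        lasso = LassoBicSelector().fit(X, y)
        entry = lasso.entry_order_
        k = self.k if self.k is not None else lasso.k_

        def ranks(scores: np.ndarray, ascending: bool) -> np.ndarray:
            s = pd.Series(scores, index=cols)
            return s.rank(ascending=ascending, method="average").to_numpy()

        avg = (ranks(corr, False) + ranks(relief, False)
               + ranks(importance, False) + ranks(entry, True)) / 4.0
        order = sorted(range(p), key=lambda j: (avg[j], cols[j]))
        self.average_rank_ = pd.Series(avg, index=cols)
        self.k_ = int(k)
        self.selected_features_ = sorted(cols[j] for j in order[:k])
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        return pd.DataFrame(X)[self.selected_features_]


def vif_stepwise_screen(X: pd.DataFrame, priority: list[str] | None = None,
                        vif_max: float = 5.0) -> tuple[list[str], pd.DataFrame]:
    """Functional wrapper over :class:`VifScreener`."""
    s = VifScreener(threshold=vif_max, priority=priority).fit(X)
    return s.kept_features_, s.report_


def lasso_bic_select(X: pd.DataFrame, y: np.ndarray) -> SelectionResult:
    """Functional wrapper over :class:`LassoBicSelector`."""
    return LassoBicSelector().fit(X, y).result()


def ensemble_rank_select(X: pd.DataFrame, y: np.ndarray,
                         k_target: int | None = None,
                         random_state: int = 0) -> list[str]:
    """Functional wrapper over :class:`EnsembleRankSelector`."""
    sel = EnsembleRankSelector(k=k_target, random_state=random_state)
    return sel.fit(X, y).selected_features_
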