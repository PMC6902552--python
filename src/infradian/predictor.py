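"""Nested leave-one-out cross-validated linear regression.

This is the pipeline's core computation.  A per-mouse scalar target (an LA
value or a gene-expression level) is predicted from the metabolome pattern
by ordinary least squares on a small set of selected metabolites, and the
selection is *nested*: for each outer fold (one held-out mouse) an inner
leave-one-out loop — run entirely on the outer training set — re-ranks
metabolites by |Pearson r| with the target on every inner split and picks
the model size ``k`` minimizing inner mean squared prediction error.  The
held-out mouse therefore influences nothing about its own model: not the
feature ranking, not the z-scoring statistics, not the fit.

The out-of-fold predictions are scored by a two-sided Pearson test against
the actual targets, and the per-metabolite selection frequency over outer
folds ("feature preference") profiles which metabolites carry the signal.

Everything here is deterministic: fixed inputs give bit-identical results.

A deliberately leaky variant (``leak_feature_ranking=True``) ranks features
once on *all* mice before cross-validating.  It exists purely as a negative
control for leakage diagnostics — its inflated false-positive rate is what
a broken pipeline looks like — and must never be used for inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .exceptions import InsufficientDataError, UndefinedCorrelationError

logger = logging.getLogger(__name__)

_MAX_K_DEFAULT = 20


@dataclass(frozen=True)
class PredictorConfig:
    """Tuning surface of the nested-LOOCV predictor.

    ``k_grid`` — candidate numbers of selected metabolites; ``None`` means
    ``1..min(max_k, n_train - 2)`` computed at fit time (OLS with intercept
    stays solvable).  Ranking statistic (|Pearson r|) and inner criterion
    (mean squared error) are fixed by design.  ``standardize`` z-scores
    features with training-fold statistics only.
    """

    k_grid: tuple[int, ...] | None = None
    standardize: bool = True
    max_k: int = _MAX_K_DEFAULT

    def resolve_k_grid(self, n_train: int) -> tuple[int, ...]:
        if self.k_grid is not None:
            grid = tuple(sorted(set(int(k) for k in self.k_grid)))
            if not grid or grid[0] < 0:
                raise ValueError("k_grid must be nonempty with nonnegative entries")
            return grid
        top = min(self.max_k, n_train - 2)
        if top < 1:
            raise InsufficientDataError(f"training size {n_train} too small for any model")
        return tuple(range(1, top + 1))


def rank_features(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column indices sorted by decreasing |Pearson r| with ``y``.

    Ties are broken by input column order (stable sort).  Zero-variance
    columns get correlation 0 and are ranked after every finite-correlation
    column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    absr = np.abs(r)
    absr[~np.isfinite(absr)] = 0.0
    key = np.where(sx == 0, -1.0, absr)  # zero-variance columns sort after all others
    return np.argsort(-key, kind="stable")


@dataclass
class LinearModelFit:
    """An OLS fit on selected, training-standardized features."""

    coef: np.ndarray           # coefficients on the standardized kept columns
    intercept: float
    kept: np.ndarray           # positions (within the supplied columns) retained after collinearity drop
    x_mean: np.ndarray
    x_scale: np.ndarray
    n_obs: int

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if len(self.kept) == 0:
            return np.full(X_new.shape[0], self.intercept)
        Z = (X_new[:, self.kept] - self.x_mean) / self.x_scale
        return self.intercept + Z @ self.coef


def fit_linear_model(X: np.ndarray, y: np.ndarray, standardize: bool = True) -> LinearModelFit:
    """Ordinary least squares with an intercept on (optionally z-scored)
    features.

    Collinear columns are dropped, keeping the earlier (better-ranked) one,
    with a logged warning.  ``k = 0`` columns gives the intercept-only model
    predicting the training mean.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n < k + 1:
        raise InsufficientDataError(f"need n >= k + 1 observations (n={n}, k={k})")
    if k == 0:
        return LinearModelFit(
            coef=np.empty(0), intercept=float(y.mean()), kept=np.empty(0, dtype=int),
            x_mean=np.empty(0), x_scale=np.empty(0), n_obs=n,
        )
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        scale = np.where(std > 0, std, 1.0)
    else:
        mean = np.zeros(k)
        scale = np.ones(k)
    Z = (X - mean) / scale

    kept = list(range(k))
    while True:
        design = np.column_stack([np.ones(n), Z[:, kept]])
        Q, R = np.linalg.qr(design)
        diag = np.abs(np.diag(R))
        tol = np.sqrt(n) * 1e-8
        bad = [j for j in range(1, len(kept) + 1) if diag[j] < tol]
        if not bad:
            break
        drop = kept[bad[0] - 1]
        logger.warning("dropping collinear feature column %d", drop)
        kept.remove(drop)
        if not kept:
            return fit_linear_model(np.empty((n, 0)), y)
    params = solve_triangular(R, Q.T @ y)
    kept_arr = np.asarray(kept, dtype=int)
    return LinearModelFit(
        coef=params[1:], intercept=float(params[0]), kept=kept_arr,
        x_mean=mean[kept_arr], x_scale=scale[kept_arr], n_obs=n,
    )


def _loo_rankings(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature rankings for every leave-one-out split of (X, y) at once.

    Row ``t`` of the returned (n, p) integer array is the |Pearson r|
    ranking computed on the data with row ``t`` removed, via sufficient
    statistics, with the same tie (input order) and zero-variance (ranked
    last) conventions as :func:`rank_features`.
    """
    n, p = X.shape
    m1 = n - 1
    Sx = X.sum(axis=0)
    Sxx = (X * X).sum(axis=0)
    Sxy = (X * y[:, None]).sum(axis=0)
    Sy = y.sum()
    Syy = float(y @ y)
    Sx_t = Sx - X
    Sxx_t = Sxx - X * X
    Sxy_t = Sxy - X * y[:, None]
    Sy_t = Sy - y
    Syy_t = Syy - y * y
    cov = Sxy_t - Sx_t * (Sy_t / m1)[:, None]
    vx = np.maximum(Sxx_t - Sx_t**2 / m1, 0.0)
    vy = np.maximum(Syy_t - Sy_t**2 / m1, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(vx * vy[:, None])
    absr = np.abs(r)
    absr[~np.isfinite(absr)] = 0.0
    scale = np.maximum(Sxx_t, 1.0)
    key = np.where(vx <= 1e-12 * scale, -1.0, absr)
    return np.argsort(-key, axis=1, kind="stable")


def _prefix_loo_mse(
    X: np.ndarray,
    y: np.ndarray,
    k_grid: Sequence[int],
    fixed_order: np.ndarray | None = None,
    standardize: bool = True,
) -> dict[int, float]:
    """Inner LOO squared errors per candidate ``k``.

    For each inner split, features are re-ranked on the inner-training rows
    (unless a leaky ``fixed_order`` is injected), the top-``k`` models for
    every ``k`` share one QR factorization of the ordered design, and the
    held-out row is predicted from each prefix model.  Rankings for all
    splits are computed in one vectorized pass over sufficient statistics.
    """
    n = len(y)
    feasible = [k for k in k_grid if k <= n - 1 - 2]
    if not feasible:
        feasible = [min(k_grid)]  # fall back to the smallest requested model
    kmax = min(max(feasible), X.shape[1])
    sqerr = {k: 0.0 for k in feasible}
    orders = None if fixed_order is not None else _loo_rankings(X, y)
    idx = np.arange(n)
    ones = np.ones(n - 1)
    for m in range(n):
        tr = idx != m
        Xi, yi = X[tr], y[tr]
        order = fixed_order if fixed_order is not None else orders[m]
        top = order[:kmax]
        Xtop = Xi[:, top]
        if standardize:
            mu = Xtop.mean(axis=0)
            sd = Xtop.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mu = np.zeros(len(top))
            sd = np.ones(len(top))
        Z = (Xtop - mu) / sd
        design = np.column_stack([ones, Z])
        Q, R = np.linalg.qr(design)
        diag = np.abs(np.diag(R))
        xh = (X[m, top] - mu) / sd
        if np.any(diag < np.sqrt(n - 1) * 1e-8):
            # rare collinear case: defer to the careful fitter per k
            for k in feasible:
                lm = fit_linear_model(Xi[:, order[:k]], yi, standardize=standardize)
                pred = lm.predict(X[m, order[:k]][None, :])[0]
                sqerr[k] += (y[m] - pred) ** 2
            continue
        c = Q.T @ yi
        # prefix predictions in one forward-substitution pass: with
        # R^T z = x_aug, the top-k model's prediction is sum_{j<=k+1} z_j c_j
        xa = np.concatenate(([1.0], xh))
        z = np.empty(kmax + 1)
        for j in range(kmax + 1):
            z[j] = (xa[j] - R[:j, j] @ z[:j]) / R[j, j]
        prefix_preds = np.cumsum(z * c[: kmax + 1])
        for k in feasible:
            pred = prefix_preds[min(k, kmax)]
            sqerr[k] += (y[m] - pred) ** 2
    return {k: v / n for k, v in sqerr.items()}


def inner_select_k(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: PredictorConfig | None = None,
    fixed_order: np.ndarray | None = None,
) -> tuple[int, dict[int, float]]:
    """Model size minimizing inner-LOO mean squared error (ties → smallest k)."""
    config = config or PredictorConfig()
    n = len(y_train)
    if n < 4:
        raise InsufficientDataError(f"inner selection needs >= 4 training mice, have {n}")
    k_grid = config.resolve_k_grid(n)
    mses = _prefix_loo_mse(X_train, y_train, k_grid, fixed_order=fixed_order, standardize=config.standardize)
    best = min(mses, key=lambda k: (mses[k], k))
    return best, mses


class NestedLOOCV:
    """Nested leave-one-out cross-validated metabolome → target regression.

    Parameters
    ----------
    endog : array-like (n,)
        Per-mouse target (24 h LA, a 3 h-window LA, or log2 expression).
    exog : array-like (n, p) or DataFrame
        Mice × metabolites feature matrix (internal standard removed, no
        missing values).
    feature_names, mouse_ids : sequences, optional
        Taken from the DataFrame when ``exog`` is one.
    config : PredictorConfig, optional
    """

    def __init__(self, endog, exog, feature_names=None, mouse_ids=None, config: PredictorConfig | None = None):
        if isinstance(exog, pd.DataFrame):
            feature_names = feature_names or [str(c) for c in exog.columns]
            mouse_ids = mouse_ids or [str(i) for i in exog.index]
            exog = exog.to_numpy(dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.endog = np.asarray(endog, dtype=float)
        n, p = self.exog.shape
        if len(self.endog) != n:
            raise ValueError(f"endog has {len(self.endog)} rows, exog {n}")
        if np.isnan(self.exog).any() or np.isnan(self.endog).any():
            raise ValueError("missing values must be handled before fitting (see exclude_incomplete_mice)")
        self.feature_names = list(feature_names) if feature_names else [f"x{j}" for j in range(p)]
        self.mouse_ids = list(mouse_ids) if mouse_ids else [str(i) for i in range(n)]
        self.config = config or PredictorConfig()

    @classmethod
    def from_dataframe(cls, features: pd.DataFrame, target: pd.Series, config: PredictorConfig | None = None):
        """Align a feature frame and a target series by mouse_id index."""
        missing = [i for i in features.index if i not in target.index]
        if missing:
            raise ValueError(f"target missing for mice: {missing}")
        y = target.loc[features.index]
        return cls(y.to_numpy(dtype=float), features, config=config)

    @property
    def nobs(self) -> int:
        return self.exog.shape[0]

    def fit(self, leak_feature_ranking: bool = False) -> "NestedLOOCVResults":
        X, y = self.exog, self.endog
        n, p = X.shape
        if n < 6:
            raise InsufficientDataError(f"nested LOOCV needs >= 6 mice, have {n}")
        if np.ptp(y) == 0:
            raise UndefinedCorrelationError("constant target: prediction correlation undefined")
        global_order = rank_features(X, y) if leak_feature_ranking else None

        preds = np.empty(n)
        fold_k: list[int] = []
        fold_features: list[list[str]] = []
        idx = np.arange(n)
        for i in range(n):
            tr = idx != i
            X_tr, y_tr = X[tr], y[tr]
            k_star, _ = inner_select_k(X_tr, y_tr, self.config, fixed_order=global_order)
            order = global_order if global_order is not None else rank_features(X_tr, y_tr)
            sel = order[:k_star]
            lm = fit_linear_model(X_tr[:, sel], y_tr, standardize=self.config.standardize)
            preds[i] = lm.predict(X[i, sel][None, :])[0]
            fold_k.append(k_star)
            fold_features.append([self.feature_names[j] for j in sel])

        counts = pd.Series(0.0, index=self.feature_names)
        for feats in fold_features:
            counts[feats] += 1.0
        preference = counts / n

        if np.ptp(preds) == 0:
            r, pval = float("nan"), float("nan")
        else:
            r, pval = stats.pearsonr(y, preds)
        return NestedLOOCVResults(
            model=self,
            fittedvalues=preds,
            actual=y.copy(),
            pearson_r=float(r),
            p_value=float(pval),
            fold_k=fold_k,
            fold_features=fold_features,
            feature_preference=preference,
            leaky=leak_feature_ranking,
        )


@dataclass
class NestedLOOCVResults:
    """Out-of-fold predictions and their evaluation.

    ``pearson_r`` / ``p_value`` score the pooled (actual, predicted) pairs
    with a two-sided Pearson test; ``feature_preference`` is the fraction
    of outer folds in which each metabolite entered the model.
    """

    model: NestedLOOCV
    fittedvalues: np.ndarray
    actual: np.ndarray
    pearson_r: float
    p_value: float
    fold_k: list[int]
    fold_features: list[list[str]]
    feature_preference: pd.Series
    leaky: bool = False

    @property
    def nobs(self) -> int:
        return len(self.actual)

    def to_frame(self) -> pd.DataFrame:
        """Per-mouse actual vs out-of-fold predicted target."""
        return pd.DataFrame(
            {"actual": self.actual, "predicted": self.fittedvalues, "chosen_k": self.fold_k},
            index=pd.Index(self.model.mouse_ids, name="mouse_id"),
        )

    def selected_features(self, min_preference: float = 0.0) -> pd.Series:
        """Feature preferences of metabolites ever selected, descending."""
        pref = self.feature_preference
        out = pref[pref > min_preference].sort_values(ascending=False)
        return out

    def summary(self) -> str:
        lines = [
            "Nested LOOCV linear regression",
            "=" * 46,
            f"{'No. mice:':<28}{self.nobs}",
            f"{'No. metabolites:':<28}{self.model.exog.shape[1]}",
            f"{'Pearson r (actual, pred):':<28}{self.pearson_r: .4f}",
            f"{'P-value (two-sided):':<28}{self.p_value: .4g}",
            f"{'Median model size k:':<28}{int(np.median(self.fold_k))}",
            f"{'Features ever selected:':<28}{int((self.feature_preference > 0).sum())}",
        ]
        if self.leaky:
            lines.append("WARNING: leaky ranking diagnostic — not valid for inference")
        top = self.selected_features().head(10)
        if len(top):
            lines.append("-" * 46)
            lines.append("Top feature preferences:")
            for name, v in top.items():
                lines.append(f"  {name:<30}{v:.3f}")
        return "\n".join(lines)
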