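"""Model comparison of the delta2 time series against rate predictors.

Six candidate generalized-least-squares regressions (null/intercept-only,
extinction, origination, mass-extinction, origination + extinction,
origination + mass-extinction) with AR(1) errors are fitted by full maximum
likelihood so their log-likelihoods — and hence AIC and Akaike weights —
are directly comparable.  A random-forest regression provides an absolute
measure of fit via out-of-bag permutation importance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "ModelFit",
    "gls_fit",
    "akaike_weights",
    "compare_models",
    "ImportanceResult",
    "rf_importance",
]

MODEL_PREDICTORS = {
    "Extinction": ("ext_rate",),
    "Origination": ("orig_rate",),
    "Mass Extinction": ("mass_ext",),
    "Origination + Extinction": ("orig_rate", "ext_rate"),
    "Origination + Mass Extinction": ("orig_rate", "mass_ext"),
    "Null": (),
}


@dataclass
class ModelFit:
    name: str
    loglik: float
    k: int
    aic: float
    coefficients: np.ndarray
    phi: float
    sigma2: float
    coef_cov: np.ndarray | None = None
    weight: float | None = None


def _ar1_whiten(y: np.ndarray, X: np.ndarray, phi: float):
    n = len(y)
    yw = np.empty(n)
    Xw = np.empty_like(X)
    c = np.sqrt(1.0 - phi**2)
    yw[0] = c * y[0]
    Xw[0] = c * X[0]
    yw[1:] = y[1:] - phi * y[:-1]
    Xw[1:] = X[1:] - phi * X[:-1]
    return yw, Xw


def _profile_loglik(y: np.ndarray, X: np.ndarray, phi: float):
    """ML log-likelihood with beta and sigma^2 profiled out, given phi."""
    n = len(y)
    yw, Xw = _ar1_whiten(y, X, phi)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        rss = 1e-300
    sigma2 = rss / n
    ll = -0.5 * n * np.log(2 * np.pi * sigma2) + 0.5 * np.log(1 - phi**2) - 0.5 * n
    return ll, beta, sigma2


def gls_fit(
    y,
    X=None,
    names: tuple[str, ...] = (),
    error_model: str = "ar1",
    name: str = "model",
    on_collinear: str = "raise",
) -> ModelFit:
    """Fit y = X beta + AR(1) noise by full maximum likelihood.

    ``X`` excludes the intercept, which is always added.  The parameter
    count k covers the identifiable coefficients, the innovation variance,
    and (for ``error_model="ar1"``) the autoregression phi, so
    AIC = 2k - 2 loglik is comparable across fixed-effect structures.
    Rank-deficient designs (e.g. an indicator that never fires, collinear
    with the intercept) are rejected by default; ``on_collinear="collapse"``
    instead fits the identifiable subspace with k reduced to the design
    rank, so a degenerate model collapses onto its nested sub-model.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 time points")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    cols = [np.ones(n)]
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        if X.shape[0] != n:
            raise ValueError("X is not aligned with y")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        cols.extend(X.T)
    M = np.column_stack(cols)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        if on_collinear == "raise":
            raise ValueError(
                f"collinear predictors in model {name!r}: design rank "
                f"{rank} < {M.shape[1]} columns"
            )
        if on_collinear != "collapse":
            raise ValueError(f"unknown on_collinear policy {on_collinear!r}")

    if error_model == "iid":
        ll, beta, sigma2 = _profile_loglik(y, M, 0.0)
        phi = 0.0
        k = rank + 1
    elif error_model == "ar1":
        res = minimize_scalar(
            lambda p: -_profile_loglik(y, M, p)[0],
            bounds=(-0.99, 0.99),
            method="bounded",
        )
        if not res.success:
            raise RuntimeError(f"AR(1) ML optimization failed: {res}")
        phi = float(res.x)
        ll, beta, sigma2 = _profile_loglik(y, M, phi)
        k = rank + 2
    else:
        raise ValueError(f"unknown error model {error_model!r}")

    yw, Mw = _ar1_whiten(y, M, phi)
    cov = sigma2 * np.linalg.pinv(Mw.T @ Mw)
    return ModelFit(
        name=name, loglik=float(ll), k=k, aic=2 * k - 2 * float(ll),
        coefficients=beta, phi=phi, sigma2=sigma2, coef_cov=cov,
    )


def akaike_weights(aics) -> np.ndarray:
    """w_i = exp(-(AIC_i - AIC_min)/2), normalized to sum to 1."""
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0:
        raise ValueError("need at least one AIC value")
    if not np.all(np.isfinite(aics)):
        raise ValueError("AIC values must be finite")
    rel = np.exp(-0.5 * (aics - aics.min()))
    return rel / rel.sum()


def compare_models(
    delta2_series: pd.DataFrame,
    rates: pd.DataFrame,
    error_model: str = "ar1",
    fixed_null_mean: float | None = None,
) -> pd.DataFrame:
    """Fit the six candidate models of the delta2 curve and weight them.

    ``delta2_series`` and ``rates`` must share the bin layout.  The null
    model estimates its mean by default; ``fixed_null_mean`` instead fits
    pure noise around the given constant (the fixed-mean variant).
    """
    if len(delta2_series) != len(rates):
        raise ValueError("delta2 series and rate series are not aligned")
    y = delta2_series["mean_delta2"].to_numpy(dtype=float)
    fits = []
    for name, predictors in MODEL_PREDICTORS.items():
        if not predictors and fixed_null_mean is not None:
            fit = gls_fit(y - fixed_null_mean, None, error_model=error_model,
                          name=name)
        else:
            X = (
                np.column_stack([rates[p].to_numpy(dtype=float) for p in predictors])
                if predictors else None
            )
            fit = gls_fit(y, X, error_model=error_model, name=name,
                          on_collinear="collapse")
        fits.append(fit)
    w = akaike_weights([f.aic for f in fits])
    for f, wi in zip(fits, w):
        f.weight = float(wi)
    df = pd.DataFrame(
        {
            "model": [f.name for f in fits],
            "loglik": [f.loglik for f in fits],
            "k": [f.k for f in fits],
            "aic": [f.aic for f in fits],
            "akaike_weight": [f.weight for f in fits],
        }
    )
    return df.sort_values("aic", ignore_index=True)


# ---------------------------------------------------------------------------
# random forest


@dataclass
class ImportanceResult:
    """Out-of-bag permutation importances of one random-forest regression."""

    predictors: list[str]
    pct_mse: np.ndarray
    node_purity: np.ndarray
    variance_explained: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "pct_mse": self.pct_mse,
                "node_purity": self.node_purity,
            }
        )


def _bootstrap_indices(estimator, n_samples: int) -> np.ndarray:
    # reproduces scikit-learn's per-tree bootstrap draw from the recorded seed
    rs = np.random.RandomState(estimator.random_state)
    return rs.randint(0, n_samples, n_samples)


def rf_importance(
    y,
    X,
    predictors: list[str] | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceResult:
    """Random-forest fit with %MSE permutation importance on OOB samples.

    ``pct_mse`` is the percent increase in out-of-bag mean squared error
    when one predictor is permuted (R randomForest's importance measure on
    the forest scale); ``node_purity`` is mean-decrease-in-impurity;
    ``variance_explained`` is the out-of-bag R^2.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n_trees < 100:
        raise ValueError("n_trees must be >= 100")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; importance is undefined")
    if predictors is None:
        predictors = [f"x{j}" for j in range(p)]

    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, p // 3),
        oob_score=True,
        bootstrap=True,
        random_state=seed,
    )
    forest.fit(X, y)

    rng = np.random.default_rng(seed)
    base_sum = np.zeros(n)
    base_cnt = np.zeros(n)
    perm_sum = np.zeros((p, n))
    for est in forest.estimators_:
        inbag = _bootstrap_indices(est, n)
        oob = np.setdiff1d(np.arange(n), inbag)
        if oob.size == 0:
            continue
        base_sum[oob] += est.predict(X[oob])
        base_cnt[oob] += 1
        for j in range(p):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            perm_sum[j, oob] += est.predict(Xp)
    seen = base_cnt > 0
    oob_pred = base_sum[seen] / base_cnt[seen]
    mse0 = float(np.mean((y[seen] - oob_pred) ** 2))
    pct = np.empty(p)
    for j in range(p):
        pred_j = perm_sum[j, seen] / base_cnt[seen]
        mse_j = float(np.mean((y[seen] - pred_j) ** 2))
        pct[j] = 100.0 * (mse_j - mse0) / mse0
    return ImportanceResult(
        predictors=list(predictors),
        pct_mse=pct,
        node_purity=forest.feature_importances_.copy(),
        variance_explained=float(forest.oob_score_),
    )
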