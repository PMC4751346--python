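"""GEBV prediction engines.

RRBLUP is implemented from first principles: the mixed model
``y = 1 mu + Z u + e`` with ``u ~ N(0, I sigma_u^2)``, variance
components by restricted maximum likelihood over the ridge penalty
``lambda = sigma_e^2 / sigma_u^2`` using the spectral decomposition of
``Z Z'``, then the dual-form marker effects
``u_hat = Z'(ZZ' + lambda I)^{-1}(y - 1 mu_hat)``.

KNN regression uses Euclidean distance on the additive codes with
deterministic tie-breaking; random-forest and gradient-boosting
regressors are thin adapters over scikit-learn pinned at the evaluated
hyperparameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold

from .genotype_io import GenotypeMatrix

__all__ = [
    "AlignmentError",
    "RRBLUPModel",
    "KNNConfig",
    "EnsembleConfig",
    "fit_rrblup",
    "predict_gebv",
    "select_k_cv",
    "predict_knn",
    "fit_predict_ensemble",
    "write_rrblup",
    "model_summary_json",
]


class AlignmentError(ValueError):
    """Training and test marker sets differ in identity or order."""


def _codes(g) -> np.ndarray:
    if isinstance(g, GenotypeMatrix):
        if g.has_missing():
            raise ValueError("impute missing genotypes before model fitting")
        return g.codes
    return np.asarray(g, dtype=float)


def _marker_ids(g):
    return list(g.marker_ids) if isinstance(g, GenotypeMatrix) else None


# ---------------------------------------------------------------------------
# RRBLUP


@dataclass
class RRBLUPModel:
    """Fitted ridge-regression BLUP: intercept, marker effects, variances."""

    mu: float
    u: np.ndarray
    sigma_u2: float
    sigma_e2: float
    lam: float
    marker_ids: list[str] | None = None


def _reml_profile(d: np.ndarray, yr: np.ndarray, xr: np.ndarray, lam: float):
    """Profiled REML pieces at a fixed penalty.

    ``d`` are eigenvalues of ZZ', ``yr``/``xr`` the rotated response and
    intercept column.  Returns (log-likelihood, mu_gls, sigma_u2).
    """
    w = 1.0 / (d + lam)
    xwx = float(np.sum(w * xr * xr))
    mu = float(np.sum(w * xr * yr) / xwx)
    r = yr - xr * mu
    ypy = float(np.sum(w * r * r))
    n = d.size
    sigma_u2 = ypy / (n - 1)
    ll = -0.5 * (
        (n - 1) * math.log(sigma_u2)
        + float(np.sum(np.log(d + lam)))
        + math.log(xwx)
    )
    return ll, mu, sigma_u2


def fit_rrblup(g_train, y_train, lam: float | None = None) -> RRBLUPModel:
    """Fit RRBLUP, estimating the ridge penalty by REML unless fixed.

    The REML criterion is maximized by golden-section search on
    ``log10 lambda in [-10, 10]`` (tolerance 1e-6), each evaluation using
    the one-off spectral decomposition of ZZ'.  ``lam=np.inf`` gives the
    infinite-penalty limit (zero marker effects, intercept = mean).
    """
    z = _codes(g_train)
    y = np.asarray(y_train, dtype=float)
    n, m = z.shape
    if n < 3:
        raise ValueError("need at least 3 training individuals")
    if y.shape != (n,):
        raise ValueError("y_train length does not match genotypes")
    if not np.isfinite(y).all() or not np.isfinite(z).all():
        raise ValueError("non-finite training values")
    ids = _marker_ids(g_train)

    if lam is not None and np.isinf(lam):
        return RRBLUPModel(float(y.mean()), np.zeros(m), 0.0, float(np.var(y, ddof=1)),
                           math.inf, ids)
    if np.ptp(y) == 0.0:
        raise ValueError("constant phenotype: variance components degenerate")

    k = z @ z.T
    d, uvec = np.linalg.eigh(k)
    d = np.clip(d, 0.0, None)
    yr = uvec.T @ y
    xr = uvec.T @ np.ones(n)

    if lam is None:
        # golden-section maximization of the REML log-likelihood
        phi = (math.sqrt(5.0) - 1.0) / 2.0
        lo, hi = -10.0, 10.0
        a = hi - phi * (hi - lo)
        b = lo + phi * (hi - lo)
        fa = _reml_profile(d, yr, xr, 10.0**a)[0]
        fb = _reml_profile(d, yr, xr, 10.0**b)[0]
        while hi - lo > 1e-6:
            if fa < fb:
                lo, a, fa = a, b, fb
                b = lo + phi * (hi - lo)
                fb = _reml_profile(d, yr, xr, 10.0**b)[0]
            else:
                hi, b, fb = b, a, fa
                a = hi - phi * (hi - lo)
                fa = _reml_profile(d, yr, xr, 10.0**a)[0]
        lam = 10.0 ** ((lo + hi) / 2.0)

    if lam <= 0:
        raise ValueError(f"ridge penalty must be positive, got {lam}")
    _, mu, sigma_u2 = _reml_profile(d, yr, xr, lam)
    w = 1.0 / (d + lam)
    resid_rot = w * (yr - xr * mu)
    u = z.T @ (uvec @ resid_rot)
    return RRBLUPModel(mu, u, sigma_u2, lam * sigma_u2, float(lam), ids)


def predict_gebv(model: RRBLUPModel, g_test) -> np.ndarray:
    """GEBV = mu + Z_test u; markers must match training in id and order."""
    ids = _marker_ids(g_test)
    if model.marker_ids is not None and ids is not None and ids != model.marker_ids:
        off = [a for a, b in zip(ids, model.marker_ids) if a != b]
        extra = set(ids) ^ set(model.marker_ids)
        raise AlignmentError(
            f"test markers do not match training markers: {sorted(extra) or off[:5]}"
        )
    z = _codes(g_test)
    if z.shape[1] != model.u.size:
        raise AlignmentError(
            f"{z.shape[1]} test markers vs {model.u.size} trained effects"
        )
    return model.mu + z @ model.u


# ---------------------------------------------------------------------------
# KNN


@dataclass
class KNNConfig:
    """Cross-validation settings for choosing the neighbor count."""

    k_grid: list[int] = field(default_factory=lambda: list(range(1, 11)))
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.k_grid:
            raise ValueError("empty k grid")
        if min(self.k_grid) < 1:
            raise ValueError("k must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("need >= 2 CV folds")


def predict_knn(g_train, y_train, g_test, k: int) -> np.ndarray:
    """Mean phenotype of the k nearest training rows (Euclidean).

    Distance ties at the k-th rank are broken by ascending training
    index (stable argsort), making the prediction deterministic.
    """
    zt = _codes(g_train)
    y = np.asarray(y_train, dtype=float)
    zs = _codes(g_test)
    n = zt.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    dist = cdist(zs, zt, metric="euclidean")
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    return y[order].mean(axis=1)


def select_k_cv(g_train, y_train, config: KNNConfig) -> int:
    """Neighbor count minimizing seeded K-fold CV mean squared error.

    Ties are broken toward the smaller k (parsimony).
    """
    z = _codes(g_train)
    y = np.asarray(y_train, dtype=float)
    n = z.shape[0]
    if config.cv_folds > n:
        raise ValueError("more folds than training individuals")
    grid = sorted(set(config.k_grid))
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    sse = {k: 0.0 for k in grid}
    usable = {k: True for k in grid}
    for tr, va in kf.split(z):
        if tr.size == 0:
            raise ValueError("fold without training neighbors")
        for k in grid:
            if k > tr.size:
                usable[k] = False
                continue
            pred = predict_knn(z[tr], y[tr], z[va], k)
            sse[k] += float(np.sum((pred - y[va]) ** 2))
    candidates = [k for k in grid if usable[k]]
    if not candidates:
        raise ValueError("no k in the grid fits every training fold")
    return min(candidates, key=lambda k: (sse[k], k))


# ---------------------------------------------------------------------------
# tree ensembles (adapters)


@dataclass
class EnsembleConfig:
    """Pinned hyperparameters of the evaluated tree ensembles."""

    rf_n_trees: int = 500
    rf_feature_fraction: float = 1.0 / 3.0
    rf_min_node: int = 5
    rf_unpruned: bool = True
    gbm_shrinkage: float = 0.01
    gbm_subsample: float = 0.5
    gbm_depth: int = 5
    gbm_n_trees: int = 1500

    def __post_init__(self) -> None:
        if min(self.rf_n_trees, self.rf_min_node, self.gbm_depth, self.gbm_n_trees) <= 0:
            raise ValueError("ensemble counts must be positive")
        for frac in (self.rf_feature_fraction, self.gbm_subsample):
            if not 0 < frac <= 1:
                raise ValueError("fractions must be in (0, 1]")
        if self.gbm_shrinkage <= 0:
            raise ValueError("shrinkage must be positive")


def fit_predict_ensemble(
    g_train, y_train, g_test,
    method: str,
    config: EnsembleConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Fit a random forest or gradient-boosted trees and predict the test set."""
    config = config or EnsembleConfig()
    zt, y, zs = _codes(g_train), np.asarray(y_train, float), _codes(g_test)
    if method == "rf":
        reg = RandomForestRegressor(
            n_estimators=config.rf_n_trees,
            max_features=config.rf_feature_fraction,
            min_samples_leaf=config.rf_min_node,
            max_depth=None if config.rf_unpruned else 10,
            random_state=seed,
            n_jobs=1,
        )
    elif method == "gbm":
        reg = GradientBoostingRegressor(
            n_estimators=config.gbm_n_trees,
            learning_rate=config.gbm_shrinkage,
            subsample=config.gbm_subsample,
            max_depth=config.gbm_depth,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown ensemble method {method!r} (use 'rf' or 'gbm')")
    reg.fit(zt, y)
    return reg.predict(zs)


# ---------------------------------------------------------------------------
# model export


def write_rrblup(model: RRBLUPModel, path) -> None:
    """Dump an RRBLUP fit: header lines then marker_id / effect rows."""
    with open(path, "w") as fh:
        fh.write(f"#mu\t{model.mu!r}\n")
        fh.write(f"#lambda\t{model.lam!r}\n")
        fh.write(f"#sigma_u2\t{model.sigma_u2!r}\n")
        fh.write(f"#sigma_e2\t{model.sigma_e2!r}\n")
        fh.write("marker_id\teffect\n")
        ids = model.marker_ids or [f"m{j}" for j in range(model.u.size)]
        for mid, eff in zip(ids, model.u):
            fh.write(f"{mid}\t{eff!r}\n")


def model_summary_json(method: str, hyperparameters: dict, seed: int | None) -> str:
    return json.dumps(
        {"method": method, "hyperparameters": hyperparameters, "seed": seed},
        indent=2,
        default=float,
    )
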