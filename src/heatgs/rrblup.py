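"""Ridge-regression BLUP (RR-BLUP) with REML variance components.

Model: y = 1*mu + Z u + e, with marker effects u ~ N(0, I sigma_u^2) and
residuals e ~ N(0, I sigma_e^2).  The ridge parameter is lambda =
sigma_e^2 / sigma_u^2.  Because lines are few and markers many, the fit
works in the n x n kernel space K = Z Z': one spectral decomposition of the
projected kernel, then a one-dimensional REML (or ML) profile over
log-lambda maximized on a grid refined by bounded Brent search.  BLUP marker
effects follow from the kernel-space solution,

    u_hat = Z' (K + lambda I)^{-1} (y - 1 mu_hat),

which coincides with the closed-form ridge estimate
(Z'Z + lambda I)^{-1} Z'(y - 1 mu_hat) with mu_hat from GLS.

Genomic estimated breeding values (GEBVs) of new lines are Z_new u_hat,
reported either centered (breeding-value scale) or with the intercept added
(trait scale).  Prediction accuracy is the Pearson correlation between GEBV
and observed phenotype.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

LAMBDA_BOUNDS = (1e-6, 1e6)


# ---------------------------------------------------------------------------
# REML / ML profile likelihood machinery (kernel space)
# ---------------------------------------------------------------------------

def _complement_basis(n: int) -> np.ndarray:
    """Orthonormal basis of the orthogonal complement of the intercept (n x n-1)."""
    return linalg.null_space(np.ones((1, n)))


def _reml_loglik(log_lam: np.ndarray, xi: np.ndarray, eta2: np.ndarray):
    """Restricted log-likelihood profile at lambda = exp(log_lam) (vectorized)."""
    lam = np.exp(np.atleast_1d(log_lam))[:, None]
    denom = xi[None, :] + lam
    s = (eta2[None, :] / denom).sum(axis=1)
    q = len(xi)
    return 0.5 * (q * np.log(q / (2 * np.pi)) - q - q * np.log(s)
                  - np.log(denom).sum(axis=1))


def _ml_loglik(log_lam: np.ndarray, xi: np.ndarray, yt: np.ndarray, xt: np.ndarray):
    lam = np.exp(np.atleast_1d(log_lam))
    n = len(yt)
    out = np.empty(len(lam))
    for k, lv in enumerate(lam):
        w = 1.0 / (xi + lv)
        xtw = xt * w[:, None]
        beta = np.linalg.solve(xt.T @ xtw, xtw.T @ yt)
        r = yt - xt @ beta
        s = (w * r * r).sum()
        out[k] = 0.5 * (n * np.log(n / (2 * np.pi)) - n - n * np.log(s)
                        - np.log(xi + lv).sum())
    return out


def _optimize_lambda(loglik, n_grid: int = 81):
    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    grid = np.linspace(lo, hi, n_grid)
    vals = loglik(grid)
    k = int(np.argmax(vals))
    a = grid[max(0, k - 1)]
    b = grid[min(n_grid - 1, k + 1)]
    res = optimize.minimize_scalar(
        lambda t: -float(loglik(np.array([t]))[0]), bounds=(a, b), method="bounded",
        options={"xatol": 1e-8},
    )
    best = res.x if -res.fun >= vals[k] else grid[k]
    return float(np.exp(best))


# ---------------------------------------------------------------------------
# Kernel-space fit used by both the estimator and the hold-out grid
# ---------------------------------------------------------------------------

@dataclass
class KernelFit:
    """Solution of the mixed model in kernel space."""

    mu: float
    lam: float
    sigma_u2: float
    sigma_e2: float
    alpha: np.ndarray  # (K + lambda I)^{-1} (y - 1 mu); gebv_new = K_new @ alpha
    h2: float          # sigma_g^2 / (sigma_g^2 + sigma_e^2) on the line scale


def fit_kernel(K: np.ndarray, y: np.ndarray, lam: float | None = None,
               method: str = "reml") -> KernelFit:
    """Fit the mixed model given the marker kernel K = Z Z' and phenotypes y."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 lines")
    if np.ptp(y) == 0:
        raise ValueError("phenotype vector is constant")
    K = np.asarray(K, dtype=float)

    scale = np.abs(np.diag(K)).mean()
    if scale < 1e-12:
        warnings.warn("kernel is (near) zero: no genetic signal representable")
        return KernelFit(float(y.mean()), np.inf, 0.0, float(y.var(ddof=1)),
                         np.zeros(n), 0.0)

    U0 = _complement_basis(n)
    A = U0.T @ K @ U0
    xi, V = np.linalg.eigh((A + A.T) / 2.0)
    xi = np.clip(xi, 0.0, None)
    eta = V.T @ (U0.T @ y)
    eta2 = eta**2

    if lam is None:
        if method == "reml":
            lam = _optimize_lambda(lambda g: _reml_loglik(g, xi, eta2))
        elif method == "ml":
            xiK, UK = np.linalg.eigh((K + K.T) / 2.0)
            xiK = np.clip(xiK, 0.0, None)
            yt = UK.T @ y
            xt = UK.T @ np.ones((n, 1))
            lam = _optimize_lambda(lambda g: _ml_loglik(g, xiK, yt, xt))
        else:
            raise ValueError(f"unknown criterion {method!r}")

    Vmat = K + lam * np.eye(n)
    cho = linalg.cho_factor(Vmat, lower=True)
    vi_y = linalg.cho_solve(cho, y)
    vi_1 = linalg.cho_solve(cho, np.ones(n))
    mu = float((np.ones(n) @ vi_y) / (np.ones(n) @ vi_1))
    alpha = linalg.cho_solve(cho, y - mu)

    q = n - 1
    denom = xi + lam
    sigma_u2 = float((eta2 / denom).sum() / q)
    at_bound = lam >= LAMBDA_BOUNDS[1] * 0.999
    if at_bound:
        sigma_u2 = 0.0
    sigma_e2 = float(lam * sigma_u2) if np.isfinite(lam) else float(y.var(ddof=1))
    if at_bound:
        sigma_e2 = float(y.var(ddof=1))

    # genetic variance on the line scale: sigma_u2 * tr(S K S) / (n - 1)
    c = float(np.trace(A)) / q
    sg2 = sigma_u2 * c
    h2 = sg2 / (sg2 + sigma_e2) if (sg2 + sigma_e2) > 0 else 0.0
    return KernelFit(mu, float(lam), sigma_u2, sigma_e2, alpha, float(h2))


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class RRBLUP:
    """Ridge-regression BLUP genomic prediction model (sklearn-style).

    Parameters
    ----------
    lam : float or None
        Fixed ridge parameter sigma_e^2/sigma_u^2; when None it is estimated
        by the ``method`` criterion.
    method : {"reml", "ml"}
        Variance-component criterion; REML is the conventional default.
    standardize : bool
        Column-standardize dosages before fitting (off by default: raw
        -1/0/1 dosages, the marker-effect convention).

    Fitted attributes: ``mu_``, ``u_`` (marker effects), ``lambda_``,
    ``sigma_u2_``, ``sigma_e2_``, ``h2_``, ``n_features_in_``,
    ``marker_ids_`` (when fitted through :func:`fit_matrix`).
    """

    def __init__(self, lam: float | None = None, method: str = "reml",
                 standardize: bool = False):
        self.lam = lam
        self.method = method
        self.standardize = standardize

    # minimal sklearn protocol -----------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"lam": self.lam, "method": self.method, "standardize": self.standardize}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # fitting ------------------------------------------------------------
    def fit(self, X, y):
        Z = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if Z.ndim != 2 or len(y) != Z.shape[0]:
            raise ValueError("X must be (n_lines, n_markers) matching y")
        if np.isnan(Z).any():
            raise ValueError("X contains missing values; impute first")
        if len(y) < 3:
            raise ValueError("need at least 3 phenotyped lines")
        if np.ptp(y) == 0:
            raise ValueError("phenotype vector is constant")

        if self.standardize:
            self._center_ = Z.mean(axis=0)
            sd = Z.std(axis=0, ddof=0)
            self._scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self._center_ = np.zeros(Z.shape[1])
            self._scale_ = np.ones(Z.shape[1])
        Zs = (Z - self._center_) / self._scale_

        K = Zs @ Zs.T
        kf = fit_kernel(K, y, lam=self.lam, method=self.method)
        self.mu_ = kf.mu
        self.lambda_ = kf.lam
        self.sigma_u2_ = kf.sigma_u2
        self.sigma_e2_ = kf.sigma_e2
        self.h2_ = kf.h2
        self.u_ = Zs.T @ kf.alpha if np.isfinite(kf.lam) else np.zeros(Z.shape[1])
        self.n_features_in_ = Z.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "u_"):
            raise RuntimeError("model is not fitted")

    def gebv(self, X, centered: bool = True) -> np.ndarray:
        """Genomic breeding values; centered (Z u) or on trait scale (mu + Z u)."""
        self._check_fitted()
        Z = np.asarray(X, dtype=float)
        if Z.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Z.shape[1]} markers, model was fitted on {self.n_features_in_}"
            )
        g = ((Z - self._center_) / self._scale_) @ self.u_
        return g if centered else self.mu_ + g

    def predict(self, X) -> np.ndarray:
        """Trait-scale prediction mu + Z u (sklearn regressor convention)."""
        return self.gebv(X, centered=False)

    def score(self, X, y) -> float:
        """Prediction accuracy: Pearson r between GEBV and phenotype."""
        return accuracy(self.gebv(X), np.asarray(y, dtype=float))


def accuracy(gebv, y) -> float:
    """Pearson correlation between GEBVs and observed phenotypes.

    Returns NaN when either vector is constant or fewer than 3 pairs exist.
    """
    gebv = np.asarray(gebv, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(gebv) | np.isnan(y))
    if ok.sum() < 3 or np.ptp(gebv[ok]) == 0 or np.ptp(y[ok]) == 0:
        return float("nan")
    return float(stats.pearsonr(gebv[ok], y[ok])[0])


# ---------------------------------------------------------------------------
# GenotypeMatrix-level wrappers
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """GEBVs for a set of lines, with accuracy where phenotypes exist."""

    line_ids: list
    gebv: np.ndarray            # centered scale
    gebv_absolute: np.ndarray   # intercept added
    accuracy: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"line_id": self.line_ids, "gebv": self.gebv, "gebv_absolute": self.gebv_absolute}
        )


def fit_matrix(gm, y, **kwargs) -> RRBLUP:
    """Fit an :class:`RRBLUP` on a GenotypeMatrix; records marker ids for alignment."""
    model = RRBLUP(**kwargs).fit(gm.dosage, y)
    model.marker_ids_ = list(gm.markers["id"])
    return model


def predict_matrix(model: RRBLUP, gm, y=None) -> PredictionResult:
    """Predict GEBVs for a GenotypeMatrix, enforcing exact marker alignment."""
    ids = list(gm.markers["id"])
    if getattr(model, "marker_ids_", None) is not None and ids != model.marker_ids_:
        offending = sorted(set(ids).symmetric_difference(model.marker_ids_))
        raise ValueError(f"marker sets differ between model and matrix: {offending[:10]}")
    g = model.gebv(gm.dosage, centered=True)
    acc = accuracy(g, y) if y is not None else float("nan")
    return PredictionResult(list(gm.line_ids), g, model.mu_ + g, acc)
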