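"""RR-BLUP / GBLUP prediction and REML variance components.

The working model is the ridge-regression BLUP

    y_train = 1 mu + Xc_train beta + eps,
    beta ~ N(0, sigma2_beta I),  eps ~ N(0, sigma2_eps I),

with Xc_train column-centered so the marker design is orthogonal to the
intercept.  All computations go through the T x T ridge matrix

    H = Xc_train Xc_train' + lambda I,   lambda = sigma2_eps / sigma2_beta,

rather than Henderson's mixed-model equations: H is always invertible for
lambda > 0, whereas the marker-based kinship matrix generally is not.

Variance components are estimated by restricted maximum likelihood with an
EMMA-style reparameterization: a single eigendecomposition of Xc Xc'
restricted to the contrast space orthogonal to the intercept, followed by a
one-dimensional bounded optimization of the profiled restricted likelihood
in log(lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "VarianceComponents",
    "reml_variance_components",
    "restricted_loglik",
    "ridge_matrix",
    "gblup_predict",
    "GBLUP",
]

LOG_LAMBDA_BOUNDS = (-10.0, 10.0)


class ConvergenceError(RuntimeError):
    """REML optimizer failed; carries the likelihood trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class VarianceComponents:
    """REML estimates for the RR-BLUP model.

    Attributes
    ----------
    sigma2_beta : float
        Common marker-effect variance.
    sigma2_eps : float
        Residual variance.
    boundary : bool
        True when log(lambda) hit a bound of the search interval, e.g. a
        pure-noise phenotype pushing lambda to its upper bound.
    """

    sigma2_beta: float
    sigma2_eps: float
    boundary: bool = False
    loglik: float = np.nan

    def __post_init__(self) -> None:
        if self.sigma2_beta <= 0:
            raise ValueError("sigma2_beta must be > 0")
        if self.sigma2_eps < 0:
            raise ValueError("sigma2_eps must be >= 0")

    @property
    def ridge(self) -> float:
        """The ridge ratio lambda = sigma2_eps / sigma2_beta."""
        return self.sigma2_eps / self.sigma2_beta


def _contrast_spectrum(y: np.ndarray, Xc: np.ndarray):
    """Eigen-spectrum of Xc Xc' on the contrast space orthogonal to 1.

    Returns (xi, eta): eigenvalues of C' (Xc Xc') C and the rotated
    response, where C is an orthonormal basis of the complement of the
    intercept (Helmert contrasts).
    """
    T = y.shape[0]
    C = linalg.helmert(T).T  # T x (T-1), orthonormal, C'1 = 0
    B = C.T @ Xc  # (T-1) x M
    A = B @ B.T
    xi, V = linalg.eigh(A)
    xi = np.clip(xi, 0.0, None)
    eta = V.T @ (C.T @ y)
    return xi, eta


def restricted_loglik(y: np.ndarray, Xc: np.ndarray, log_lambda: float,
                      _spectrum=None) -> float:
    """Profiled restricted log-likelihood of the RR-BLUP model at log(lambda).

    sigma2_beta is profiled out analytically; the value is comparable
    across log_lambda for fixed (y, Xc).
    """
    xi, eta = _spectrum if _spectrum is not None else _contrast_spectrum(y, Xc)
    lam = np.exp(log_lambda)
    w = xi + lam
    n = xi.size
    s2b = float(np.sum(eta**2 / w) / n)
    return -0.5 * (n * (np.log(2 * np.pi * s2b) + 1) + float(np.sum(np.log(w))))


def reml_variance_components(y_train: np.ndarray, Xc_train: np.ndarray,
                             tol: float = 1e-8) -> VarianceComponents:
    """REML estimates of (sigma2_beta, sigma2_eps) for the RR-BLUP model.

    One eigendecomposition of the centered-design cross-product, then a
    bounded Brent search of the profiled restricted likelihood in
    log(lambda) on [-10, 10].  Solutions at the bounds are flagged as
    ``boundary`` (lambda at the upper bound means no detectable marker
    signal).
    """
    y_train = np.asarray(y_train, dtype=float).ravel()
    Xc_train = np.asarray(Xc_train, dtype=float)
    T = y_train.shape[0]
    if T < 3:
        raise ValueError("need at least 3 training individuals for REML")
    if np.ptp(y_train) == 0:
        raise ValueError("constant phenotype: variance components undefined")
    spectrum = _contrast_spectrum(y_train, Xc_train)

    trace: list[tuple[float, float]] = []

    def neg_ll(log_lam: float) -> float:
        val = restricted_loglik(y_train, Xc_train, log_lam, _spectrum=spectrum)
        trace.append((log_lam, val))
        return -val

    res = optimize.minimize_scalar(
        neg_ll, bounds=LOG_LAMBDA_BOUNDS, method="bounded",
        options={"xatol": tol, "maxiter": 500})
    if not res.success:
        raise ConvergenceError("REML bounded search did not converge", trace)
    log_lam = float(res.x)
    # minimize_scalar never evaluates exactly at the bounds; snap if the
    # optimum is within sqrt(xatol) of one.
    edge = np.sqrt(tol) * 10
    boundary = (log_lam - LOG_LAMBDA_BOUNDS[0] < edge
                or LOG_LAMBDA_BOUNDS[1] - log_lam < edge)
    if boundary:
        log_lam = (LOG_LAMBDA_BOUNDS[0]
                   if log_lam - LOG_LAMBDA_BOUNDS[0] < edge
                   else LOG_LAMBDA_BOUNDS[1])
    lam = np.exp(log_lam)
    xi, eta = spectrum
    s2b = float(np.sum(eta**2 / (xi + lam)) / xi.size)
    return VarianceComponents(sigma2_beta=s2b, sigma2_eps=s2b * lam,
                              boundary=boundary, loglik=float(-res.fun))


def ridge_matrix(Xc_train: np.ndarray, vc: VarianceComponents) -> np.ndarray:
    """H = Xc Xc' + lambda I; symmetric positive definite for lambda > 0."""
    lam = vc.ridge
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError(f"ridge ratio must be finite and > 0, got {lam}")
    T = Xc_train.shape[0]
    return Xc_train @ Xc_train.T + lam * np.eye(T)


def gblup_predict(y_train: np.ndarray, design, vc: VarianceComponents
                  ) -> np.ndarray:
    """Predicted test genetic values Xc_test Xc_train' H^{-1} (y - ybar).

    The intercept is absorbed by centering the training phenotype, which
    is exact because the design columns are orthogonal to the intercept.
    """
    y_train = np.asarray(y_train, dtype=float).ravel()
    H = ridge_matrix(design.Xc_train, vc)
    yc = y_train - y_train.mean()
    w = linalg.solve(H, yc, assume_a="pos")
    return design.Xc_test @ (design.Xc_train.T @ w)


class GBLUP(RegressorMixin, BaseEstimator):
    """Genomic BLUP regressor over allele dosages.

    Fits the RR-BLUP ridge model with REML variance components (or a fixed
    ridge ratio) and predicts genetic values of new individuals through the
    ridge matrix H.  Dosage columns are centered internally with the
    training column means.

    Parameters
    ----------
    ridge : float or None
        Fixed ridge ratio lambda = sigma2_eps / sigma2_beta.  None (default)
        estimates it by REML.

    Attributes
    ----------
    vc_ : VarianceComponents
        Estimated (or supplied) variance components.
    marker_effects_ : ndarray of shape (n_markers,)
        BLUP marker effects Xc' H^{-1} (y - ybar).
    column_means_ : ndarray
        Training column means used for centering.
    intercept_ : float
        Training phenotype mean.
    """

    def __init__(self, ridge: float | None = None):
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.column_means_ = X.mean(axis=0)
        Xc = X - self.column_means_
        if self.ridge is None:
            self.vc_ = reml_variance_components(y, Xc)
        else:
            if self.ridge <= 0:
                raise ValueError("ridge must be > 0")
            self.vc_ = VarianceComponents(sigma2_beta=1.0,
                                          sigma2_eps=float(self.ridge))
        H = ridge_matrix(Xc, self.vc_)
        self.intercept_ = float(y.mean())
        w = linalg.solve(H, y - self.intercept_, assume_a="pos")
        self.marker_effects_ = Xc.T @ w
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return self.intercept_ + (X - self.column_means_) @ self.marker_effects_
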