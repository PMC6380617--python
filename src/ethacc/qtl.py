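"""Causal-QTL model estimation: MLMM forward-selection GWAS and penalized
regression locators, followed by OLS effect estimation.

The causal model is a fixed-effect linear model y = 1 mu + Q theta + e with
a finite set of QTLs.  Two-step estimation: a multi-locus method *locates*
the QTLs (their penalized/mixed-model effect estimates are discarded as
biased), then the effects theta and residual variance sigma2_e are
re-estimated jointly by ordinary least squares.

The selected locator is the MLMM forward scan: a marker-by-marker mixed
model with a VanRaden kinship polygenic term and no structure covariates;
at each step the minimum-p marker joins the fixed effects and the rest are
rescanned, until the polygenic variance ratio (pseudo-heritability) is
close to zero or the QTL cap is reached.  Within a step, variance
components are held at the null fit (P3D); they are re-estimated whenever
a cofactor is added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import enet_path, lasso_path
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, check_X_y

from .panel import GenotypePanel, vanraden_kinship

__all__ = [
    "CausalModel",
    "ScanResult",
    "KinshipREML",
    "gwas_scan",
    "mlmm_forward",
    "MLMMSelector",
    "penalized_locate",
    "fit_causal_ols",
]


@dataclass
class CausalModel:
    """A fitted causal-QTL model y = 1 mu + Q theta + e."""

    qtl_indices: np.ndarray
    theta: np.ndarray
    intercept: float
    sigma2_e: float
    method: str = "mlmm"

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        if len(np.unique(self.qtl_indices)) != self.qtl_indices.size:
            raise ValueError("duplicate QTL indices")
        if self.qtl_indices.size != self.theta.size:
            raise ValueError("qtl_indices and theta length mismatch")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be >= 0")

    @property
    def n_qtl(self) -> int:
        return self.qtl_indices.size

    def genetic_values(self, dosages: np.ndarray) -> np.ndarray:
        """Q theta for the given dosage rows (no intercept)."""
        return dosages[:, self.qtl_indices] @ self.theta


@dataclass
class ScanResult:
    """One marker-by-marker scan around a polygenic null model."""

    p_values: np.ndarray
    effect_estimates: np.ndarray
    pseudo_h2: float
    cofactors: np.ndarray = field(default_factory=lambda: np.array([], int))


@dataclass
class KinshipREML:
    """REML fit of y = X b + u + e with u ~ N(0, s2u K), e ~ N(0, s2res I).

    Built on a one-time eigendecomposition of K; the rotated system is a
    weighted least squares with weights (xi_j + delta), delta = s2res/s2u.
    """

    sigma2_u: float
    sigma2_res: float
    delta: float
    beta: np.ndarray
    loglik: float

    @property
    def pseudo_h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_res)


_LOG_DELTA_BOUNDS = (-10.0, 10.0)


def _wls(Xr: np.ndarray, yr: np.ndarray, w: np.ndarray):
    """Weighted LS of rotated system; returns (beta, rss, logdet XtWinvX)."""
    sw = 1.0 / np.sqrt(w)
    Xw = Xr * sw[:, None]
    yw = yr * sw
    XtX = Xw.T @ Xw
    beta = linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sign, logdet = np.linalg.slogdet(XtX)
    return beta, rss, logdet


def reml_kinship(y: np.ndarray, X_fixed: np.ndarray, xi: np.ndarray,
                 U: np.ndarray, tol: float = 1e-6) -> KinshipREML:
    """EMMA-style REML for a kinship mixed model.

    Parameters
    ----------
    xi, U : eigendecomposition K = U diag(xi) U' (computed once upstream).
    """
    n, q = X_fixed.shape
    yr = U.T @ y
    Xr = U.T @ X_fixed
    _, logdet_xtx = np.linalg.slogdet(X_fixed.T @ X_fixed)

    def neg_restricted_ll(log_delta: float) -> float:
        w = xi + np.exp(log_delta)
        _, rss, logdet_w = _wls(Xr, yr, w)
        s2u = rss / (n - q)
        ll = -0.5 * ((n - q) * (np.log(2 * np.pi * s2u) + 1)
                     + float(np.sum(np.log(w))) + logdet_w - logdet_xtx)
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=_LOG_DELTA_BOUNDS, method="bounded",
        options={"xatol": tol, "maxiter": 500})
    if not res.success:
        raise RuntimeError("kinship REML did not converge")
    delta = float(np.exp(res.x))
    w = xi + delta
    beta, rss, _ = _wls(Xr, yr, w)
    s2u = rss / (n - q)
    return KinshipREML(sigma2_u=s2u, sigma2_res=s2u * delta, delta=delta,
                       beta=beta, loglik=float(-res.fun))


def gwas_scan(y: np.ndarray, panel_subset: GenotypePanel, K: np.ndarray,
              cofactors: np.ndarray | None = None,
              _eig=None) -> ScanResult:
    """Marker-by-marker mixed-model association scan.

    The null model has an intercept, the cofactor markers as fixed effects,
    and a polygenic term with covariance proportional to K.  Each remaining
    marker is tested by a 1-df F test of its effect added to the null, with
    variance components held at the null REML fit (P3D within the scan).
    Cofactor or collinear markers get NaN p-values.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = panel_subset.dosages
    n, M = X.shape
    cof = (np.array([], dtype=int) if cofactors is None
           else np.asarray(cofactors, dtype=int))
    if _eig is None:
        xi, U = linalg.eigh(K)
        xi = np.clip(xi, 0.0, None)
    else:
        xi, U = _eig
    X_fixed = np.column_stack([np.ones(n)] + [X[:, j] for j in cof])
    if np.linalg.matrix_rank(X_fixed) < X_fixed.shape[1]:
        raise ValueError("cofactors collinear with the intercept")
    fit = reml_kinship(y, X_fixed, xi, U)

    w = xi + fit.delta
    sw = 1.0 / np.sqrt(w)
    yr = (U.T @ y) * sw
    X0 = (U.T @ X_fixed) * sw[:, None]
    Xm = (U.T @ X) * sw[:, None]  # all rotated, whitened markers

    q0 = X0.shape[1]
    Q, _ = np.linalg.qr(X0)
    r0 = yr - Q @ (Q.T @ yr)
    rss0 = float(r0 @ r0)
    # residualize every marker against the null fixed effects at once
    Xm_res = Xm - Q @ (Q.T @ Xm)
    mm = np.einsum("ij,ij->j", Xm_res, Xm_res)
    my = Xm_res.T @ r0

    df = n - q0 - 1
    pvals = np.full(M, np.nan)
    effects = np.full(M, np.nan)
    testable = np.ones(M, dtype=bool)
    testable[cof] = False
    # markers collinear with the null design have ~zero residual norm
    tol = 1e-10 * max(1.0, float(mm.max()) if M else 1.0)
    degenerate = mm <= tol
    n_collinear = int((testable & degenerate).sum())
    if n_collinear:
        warnings.warn(f"{n_collinear} marker(s) collinear with the null "
                      "model: p-value NaN", stacklevel=2)
    ok = testable & ~degenerate
    b = my[ok] / mm[ok]
    rss1 = rss0 - my[ok]**2 / mm[ok]
    rss1 = np.clip(rss1, np.finfo(float).tiny, None)
    F = (rss0 - rss1) / (rss1 / df)
    pvals[ok] = stats.f.sf(F, 1, df)
    effects[ok] = b
    return ScanResult(p_values=pvals, effect_estimates=effects,
                      pseudo_h2=fit.pseudo_h2, cofactors=cof)


def mlmm_forward(y: np.ndarray, panel_subset: GenotypePanel,
                 K: np.ndarray | None = None, max_qtls: int | None = None,
                 h2_stop: float = 0.01) -> CausalModel:
    """Forward-selection multi-locus mixed-model QTL search.

    Iterates ``gwas_scan``: while the null model's pseudo-heritability is
    at least ``h2_stop`` and fewer than ``max_qtls`` cofactors are in the
    model, the marker with the minimum p-value (ties broken by lowest
    column index) is added as a fixed effect and the rest are rescanned.
    The selected markers' effects are then re-estimated by OLS.
    """
    y = np.asarray(y, dtype=float).ravel()
    T = y.size
    if K is None:
        K = vanraden_kinship(panel_subset)
    if max_qtls is None:
        max_qtls = T // 10
    if max_qtls > T - 2:
        raise ValueError("max_qtls must be at most T - 2")
    xi, U = linalg.eigh(K)
    xi = np.clip(xi, 0.0, None)
    eig = (xi, U)
    cof: list[int] = []
    while len(cof) < max_qtls:
        scan = gwas_scan(y, panel_subset, K,
                         cofactors=np.array(cof, dtype=int), _eig=eig)
        if scan.pseudo_h2 < h2_stop:
            break
        p = scan.p_values
        if np.all(np.isnan(p)):
            break
        best = int(np.nanargmin(p))  # nanargmin takes the lowest index on ties
        cof.append(best)
    model = fit_causal_ols(y, panel_subset.dosages[:, cof])
    # map the OLS fit's surviving column positions back to panel indices
    idx = np.array(cof, dtype=int)[model.qtl_indices] if cof else \
        np.array([], dtype=int)
    return CausalModel(idx, model.theta, model.intercept, model.sigma2_e,
                       method="mlmm")


class MLMMSelector(SelectorMixin, BaseEstimator):
    """sklearn-style wrapper for the MLMM forward QTL search.

    ``fit(X, y)`` runs the forward scan on a dosage matrix; the selected
    marker mask is exposed through ``get_support`` so the selector slots
    into sklearn pipelines.  ``causal_model_`` carries the OLS-refit model.

    Parameters
    ----------
    max_qtls : int or None
        Cap on the number of selected markers; None uses floor(T/10).
    h2_stop : float
        Stop when the null model's pseudo-heritability falls below this.
    """

    def __init__(self, max_qtls: int | None = None, h2_stop: float = 0.01):
        self.max_qtls = max_qtls
        self.h2_stop = h2_stop

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        panel = GenotypePanel(
            X, [f"s{i}" for i in range(X.shape[0])],
            [f"m{j}" for j in range(X.shape[1])])
        self.causal_model_ = mlmm_forward(
            y, panel, max_qtls=self.max_qtls, h2_stop=self.h2_stop)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.causal_model_.qtl_indices] = True
        return mask


def penalized_locate(y: np.ndarray, panel_subset: GenotypePanel,
                     method: str = "lasso", alpha: float = 1.0,
                     lambda_rule: str = "cv_min", folds: int = 10,
                     seed: int = 0, n_lambdas: int = 100) -> np.ndarray:
    """Locate QTLs by a coordinate-descent lasso / elastic-net path.

    The shrinkage parameter is chosen over a k-fold CV curve: ``cv_min``
    takes the lambda minimizing the mean fold MSE, ``cv_1se`` the largest
    lambda whose mean MSE is within one standard error of that minimum
    (sparser).  Only the *locations* (nonzero coefficients at the chosen
    lambda, refit on the full data) are returned; effects are re-estimated
    by OLS downstream.

    ``alpha`` is the elastic-net mixing weight in (0, 1]; it is forced to 1
    for ``method='lasso'``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = panel_subset.dosages
    n = y.size
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"{n} samples cannot be split into {folds} folds")
    if method == "lasso":
        alpha = 1.0
    elif method != "en":
        raise ValueError(f"unknown penalized method {method!r}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if lambda_rule not in ("cv_min", "cv_1se"):
        raise ValueError(f"unknown lambda rule {lambda_rule!r}")

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    # lambda path from the full data, reused in every fold
    lambdas, _, _ = enet_path(Xc, yc, l1_ratio=alpha, n_alphas=n_lambdas)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    mse = np.zeros((folds, lambdas.size))
    for k, (tr, te) in enumerate(kf.split(Xc)):
        mu_x, mu_y = Xc[tr].mean(axis=0), yc[tr].mean()
        _, coefs, _ = enet_path(Xc[tr] - mu_x, yc[tr] - mu_y,
                                l1_ratio=alpha, alphas=lambdas)
        pred = (Xc[te] - mu_x) @ coefs + mu_y
        mse[k] = np.mean((yc[te, None] - pred)**2, axis=0)
    mean_mse = mse.mean(axis=0)
    se = mse.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(mean_mse))
    if lambda_rule == "cv_min":
        i_sel = i_min
    else:
        # lambdas are decreasing; the largest within one SE is the first
        within = np.flatnonzero(mean_mse <= mean_mse[i_min] + se[i_min])
        i_sel = int(within[0])
    _, coefs_full, _ = enet_path(Xc, yc, l1_ratio=alpha,
                                 alphas=lambdas[[i_sel]])
    return np.flatnonzero(np.abs(coefs_full[:, 0]) > 0)


def fit_causal_ols(y: np.ndarray, Q_train: np.ndarray) -> CausalModel:
    """OLS fit of the causal model y = 1 mu + Q theta + e.

    All selected QTL effects are estimated together; sigma2_e is the
    residual mean square with T - p - 1 degrees of freedom.  Collinear QTL
    columns are dropped (with a warning) before fitting.
    """
    y = np.asarray(y, dtype=float).ravel()
    Q = np.asarray(Q_train, dtype=float)
    if Q.ndim == 1:
        Q = Q[:, None]
    T, p = Q.shape if Q.size else (y.size, 0)
    if p == 0:
        return CausalModel(np.array([], dtype=int), np.array([]),
                           float(y.mean()), float(y.var(ddof=1)), "ols")
    if p > T - 2:
        raise ValueError("more QTLs than T - 2")
    D = np.column_stack([np.ones(T), Q])
    keep = np.arange(p)
    # drop columns that do not increase the design rank
    if np.linalg.matrix_rank(D) < D.shape[1]:
        kept: list[int] = []
        base = np.ones((T, 1))
        for j in range(p):
            trial = np.column_stack([base, Q[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                kept.append(j)
                base = trial
        if not kept:
            raise ValueError("causal design rank-deficient after drops")
        warnings.warn(f"dropped {p - len(kept)} collinear QTL column(s)",
                      stacklevel=2)
        keep = np.array(kept, dtype=int)
        D = np.column_stack([np.ones(T), Q[:, keep]])
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    dof = T - len(keep) - 1
    s2e = float(resid @ resid) / dof
    return CausalModel(keep, coef[1:], float(coef[0]), s2e, "ols")
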