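"""Given-training-set estimators of genomic prediction accuracy.

Four quantities share one question — how well will GBLUP trained on *this*
training set predict *these* test individuals?

* ``ts_accuracy``: the empirical answer, Pearson correlation between
  observed test phenotypes and their GBLUP.  Needs test phenotypes, so it
  is only available in evaluation settings.
* ``cd_accuracy`` / ``pev_accuracy``: mixed-model answers that identify
  the causal model with the marker model (every marker a QTL with iid
  Gaussian effects).  They are algebraically the same number, since
  CD = 1 - PEV/Var for a BLUP.
* ``ethacc``: the theoretical accuracy of the RR-BLUP predictor under a
  *fixed* causal-QTL model (a finite set of QTLs with fixed effects),
  evaluated with an estimated causal model.  This separation of the
  instrumental prediction model from the causal model is what lets it
  track the realized accuracy in structured panels where CD/PEV
  systematically overestimate it.
* ``cdmean``: the training-set design criterion — the mean coefficient of
  determination of the contrast between each test individual's genetic
  value and the combined (test + training) population mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .gblup import VarianceComponents, ridge_matrix
from .panel import CenteredDesign, GenotypePanel, TrainTestSplit
from .qtl import CausalModel

__all__ = [
    "AccuracyEstimate",
    "EthAccInputs",
    "ts_accuracy",
    "cd_accuracy",
    "pev_accuracy",
    "ethacc",
    "cdmean",
]


@dataclass
class AccuracyEstimate:
    """A scalar accuracy with method tag and per-test diagnostics."""

    value: float
    method: str
    per_test: np.ndarray | None = None
    components: dict = field(default_factory=dict)


def ts_accuracy(u_hat_test: np.ndarray, y_test: np.ndarray) -> AccuracyEstimate:
    """Empirical test-set accuracy: Pearson r(y_test, predicted values)."""
    u = np.asarray(u_hat_test, dtype=float).ravel()
    y = np.asarray(y_test, dtype=float).ravel()
    if u.size != y.size:
        raise ValueError("length mismatch")
    if u.size < 3:
        raise ValueError("need at least 3 test individuals")
    if np.ptp(u) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(y, u)[0, 1])
    return AccuracyEstimate(r, "TS")


def _cd_per_test(design: CenteredDesign, vc: VarianceComponents):
    """Per-test CD_i and Var(u_i) under the GBLUP model of the genetic value.

    CD_i = (x_i' Xc' H^{-1} Xc x_i) / (x_i' x_i);  Var(u_i) = s2b x_i'x_i.
    """
    Xc, Xt = design.Xc_train, design.Xc_test
    H = ridge_matrix(Xc, vc)
    # columns of G are H^{-1} Xc x_i
    G = linalg.solve(H, Xc @ Xt.T, assume_a="pos")
    num = np.einsum("ij,ji->i", Xt @ Xc.T, G)
    xx = np.einsum("ij,ij->i", Xt, Xt)
    cd = np.zeros(Xt.shape[0])
    nz = xx > 0
    if not nz.all():
        warnings.warn("test individual(s) identical to the training mean: "
                      "CD contribution set to 0", stacklevel=3)
    cd[nz] = num[nz] / xx[nz]
    cd = np.clip(cd, 0.0, 1.0)
    var_u = vc.sigma2_beta * xx
    return cd, var_u


def cd_accuracy(design: CenteredDesign, vc: VarianceComponents,
                sqrt_link: bool = True) -> AccuracyEstimate:
    """Accuracy estimate from the coefficient of determination of each test.

    Averages sqrt(h_i^2 * CD_i) over test individuals, where
    h_i^2 = Var(u_i) / (Var(u_i) + sigma2_eps) links the genetic-value
    accuracy to the phenotype-level accuracy.  ``sqrt_link=False`` drops
    the square root (the literal no-radical reading).
    """
    cd, var_u = _cd_per_test(design, vc)
    h2 = np.divide(var_u, var_u + vc.sigma2_eps,
                   out=np.zeros_like(var_u), where=(var_u + vc.sigma2_eps) > 0)
    terms = h2 * cd
    if sqrt_link:
        terms = np.sqrt(terms)
    return AccuracyEstimate(float(terms.mean()), "CD", per_test=cd)


def pev_accuracy(design: CenteredDesign, vc: VarianceComponents,
                 sqrt_link: bool = True) -> AccuracyEstimate:
    """Accuracy estimate from the prediction error variance of each test.

    PEV_i = Var(u_i) - s2b x_i' Xc' H^{-1} Xc x_i and the averaged term is
    sqrt(h_i^2 (1 - PEV_i / Var(u_i))) — numerically identical to
    ``cd_accuracy`` through the BLUP identity CD = 1 - PEV/Var.
    """
    cd, var_u = _cd_per_test(design, vc)
    pev = var_u * (1.0 - cd)
    h2 = np.divide(var_u, var_u + vc.sigma2_eps,
                   out=np.zeros_like(var_u), where=(var_u + vc.sigma2_eps) > 0)
    ratio = np.divide(pev, var_u, out=np.ones_like(pev), where=var_u > 0)
    terms = h2 * (1.0 - ratio)
    if sqrt_link:
        terms = np.sqrt(np.clip(terms, 0.0, None))
    return AccuracyEstimate(float(terms.mean()), "PEV", per_test=pev)


@dataclass
class EthAccInputs:
    """Everything the theoretical-accuracy formula consumes.

    QTL genotype columns are centered with the same training column means
    as the SNP design (they are a subset of its columns).
    """

    design: CenteredDesign
    causal: CausalModel
    Qc_train: np.ndarray
    Qc_test: np.ndarray
    vc: VarianceComponents

    @classmethod
    def from_causal_model(cls, design: CenteredDesign, causal: CausalModel,
                          vc: VarianceComponents) -> "EthAccInputs":
        idx = np.asarray(causal.qtl_indices, dtype=int)
        return cls(design, causal, design.Xc_train[:, idx],
                   design.Xc_test[:, idx], vc)


def ethacc(inputs: EthAccInputs, ddof: int = 0) -> AccuracyEstimate:
    """Estimated theoretical accuracy of GBLUP under a causal-QTL model.

    With H the ridge matrix of the training design, theta the causal
    effects, and expectations over a random test individual replaced by
    sample moments over the observed test set:

        numerator = theta' A Xc' H^{-1} Q theta,
                    A = Cov_test(q, x)  (QTL-by-SNP cross-covariance)
        noise     = sigma2_e * mean_i || H^{-1} Xc x_i ||^2
        dispersion = w' Var(x_test) w,   w = Xc' H^{-1} Q theta
        value = numerator / sqrt(noise + dispersion) / sqrt(s2g + sigma2_e)

    where s2g is the sample variance of the test genetic values q_i' theta.
    The theoretical quantity is a correlation, so every test-population
    moment is a *centered* sample moment; the Cauchy-Schwarz inequality
    then bounds the value by 1 in magnitude even when the test set's mean
    genotype drifts far from the training mean (structured panels).
    ``ddof=0`` (default) uses divisor n_test everywhere, matching the
    plug-in sample-estimate convention; ``ddof=1`` is available.
    """
    d, vc = inputs.design, inputs.vc
    theta = np.asarray(inputs.causal.theta, dtype=float).ravel()
    p = theta.size
    s2e = inputs.causal.sigma2_e
    if p == 0:
        warnings.warn("empty causal model: EthAcc defined as 0", stacklevel=2)
        return AccuracyEstimate(0.0, "EthAcc")
    Xt = d.Xc_test
    n_test = Xt.shape[0]
    Qt, Qtr = inputs.Qc_test, inputs.Qc_train

    H = ridge_matrix(d.Xc_train, vc)
    HinvQth = linalg.solve(H, Qtr @ theta, assume_a="pos")  # H^{-1} Q theta

    HinvXx = linalg.solve(H, d.Xc_train @ Xt.T, assume_a="pos")  # T x n_test
    noise_term = s2e * float(np.mean(np.sum(HinvXx**2, axis=0)))

    w = d.Xc_train.T @ HinvQth                               # M-vector
    proj = (Xt - Xt.mean(axis=0)) @ w
    denom_n = n_test - ddof
    dispersion = float(np.sum(proj**2) / denom_n)

    g = Qt @ theta
    # theta' A w with A the test-sample cross-covariance of (q, x):
    # equals Cov_test(g, x'w)
    numerator = float(np.sum((g - g.mean()) * proj) / denom_n)
    s2g = float(np.sum((g - g.mean())**2) / denom_n)
    if s2g + s2e <= 0:
        raise ValueError("degenerate causal model: s2g + sigma2_e = 0")
    denom = np.sqrt(noise_term + dispersion) * np.sqrt(s2g + s2e)
    value = 0.0 if denom == 0 else numerator / denom
    return AccuracyEstimate(
        value, "EthAcc",
        components={"numerator": numerator, "noise_term": noise_term,
                    "signal_dispersion_term": dispersion,
                    "sigma2_g": s2g, "sigma2_e": s2e})


def cdmean(panel: GenotypePanel, split: TrainTestSplit,
           vc_panel: VarianceComponents) -> AccuracyEstimate:
    """Mean CD of contrasts between test genetic values and the combined mean.

    The combined set is the current training set plus the test set; its
    dosage columns are centered on the combined set, since the contrast
    c_i = e_i - 1/N targets the combined-population mean.  Variance
    components come from a single REML fit on the entire candidate panel
    (``vc_panel``), not from the current training set.

    CD(c_i) = (c_i' B c_i) / (c_i' G c_i) with
    B = Xall Xtr' H^{-1} Xtr Xall', G = Xall Xall', H from the training
    rows of the combined-centered design.
    """
    if len(split.train_idx) == 0:
        raise ValueError("empty training set")
    all_idx = np.concatenate([split.train_idx, split.test_idx])
    X_all = panel.dosages[all_idx]
    Xc_all = X_all - X_all.mean(axis=0)
    T = len(split.train_idx)
    N = Xc_all.shape[0]
    Xc_tr = Xc_all[:T]
    H = ridge_matrix(Xc_tr, vc_panel)

    # rows of P are (H^{-1} Xtr Xall' )' ; B = (Xall Xtr') P
    P = linalg.solve(H, Xc_tr @ Xc_all.T, assume_a="pos")
    S = Xc_all @ Xc_tr.T
    cds = np.zeros(N - T)
    for k in range(N - T):
        i = T + k
        c = -np.full(N, 1.0 / N)
        c[i] += 1.0
        Xall_c = Xc_all.T @ c          # M-vector
        b = float((S.T @ c) @ (P @ c))
        g = float(Xall_c @ Xall_c)
        if g == 0:
            warnings.warn("zero-variance contrast: CD contribution 0",
                          stacklevel=2)
            cds[k] = 0.0
        else:
            cds[k] = min(max(b / g, 0.0), 1.0)
    return AccuracyEstimate(float(cds.mean()), "CDmean", per_test=cds)
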