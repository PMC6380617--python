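"""Hill-climbing training-set optimization with exchange moves.

A move draws one member of the current training set and one non-member of
the candidate pool uniformly at random, swaps them, and re-evaluates the
criterion; the swap is kept only on strict improvement (and only if the
criterion does not reject the candidate set).  There is no stopping rule:
exactly ``n_moves`` exchanges are attempted, mirroring a fixed evaluation
budget, and the training-set size is conserved throughout.

Criteria:

* ``cdmean_criterion`` — mean contrast CD with variance components fixed
  from a single REML fit on the entire candidate panel.
* ``ethacc_criterion`` — the full per-set pipeline: REML on the current
  training set, MLMM causal-QTL rediscovery on the current training set,
  then EthAcc.  It requires a unit-variance phenotype and rejects any
  training set whose estimated causal model gives the test individuals a
  predicted genetic-value variance of 1 or more — the guard against
  "false positive" training sets whose apparent genetic variance exceeds
  the phenotypic variance.
* ``ts_oracle_criterion`` — the realized test-set accuracy itself; needs
  test phenotypes, so it is an evaluation-only oracle used to build
  optimal starting sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accuracy import EthAccInputs, cdmean, ethacc, ts_accuracy
from .gblup import VarianceComponents, gblup_predict, reml_variance_components
from .panel import GenotypePanel, Phenotype, TrainTestSplit, center_design
from .qtl import mlmm_forward

__all__ = [
    "OptimizationResult",
    "Rejected",
    "hill_climb",
    "ethacc_criterion",
    "cdmean_criterion",
    "ts_oracle_criterion",
]


class Rejected:
    """Sentinel a criterion returns to veto a candidate training set."""

    __slots__ = ("reason",)

    def __init__(self, reason: str = ""):
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover
        return f"Rejected({self.reason!r})"


@dataclass
class OptimizationResult:
    """Trajectory and outcome of one hill climb."""

    final_train_idx: np.ndarray
    start_train_idx: np.ndarray
    criterion_trace: list[tuple[int, float, bool, bool]]
    n_moves: int
    seed: int
    criterion: str = ""

    @property
    def best_value(self) -> float:
        accepted = [v for _, v, acc, _ in self.criterion_trace if acc]
        if accepted:
            return accepted[-1]
        return self.start_value

    @property
    def start_value(self) -> float:
        return self.criterion_trace[0][1] if self.criterion_trace else np.nan


def hill_climb(criterion_fn, start: np.ndarray, candidates: np.ndarray,
               n_moves: int = 5000, rng_seed: int = 0,
               criterion_name: str = "") -> OptimizationResult:
    """Maximize a training-set criterion by random exchange moves.

    ``criterion_fn`` maps an index array to a float or a ``Rejected``
    sentinel.  Each of the ``n_moves`` moves swaps a uniformly drawn
    member for a uniformly drawn non-member and accepts the swap only if
    the criterion strictly improves and is not rejected; a rejected or
    non-improving evaluation is recorded and reverted.  Move 0 in the
    trace is the evaluation of the starting set.
    """
    start = np.asarray(start, dtype=int)
    candidates = np.asarray(candidates, dtype=int)
    if not set(start.tolist()) <= set(candidates.tolist()):
        raise ValueError("start must be a subset of candidates")
    if n_moves < 0:
        raise ValueError("n_moves must be >= 0")
    outside = np.setdiff1d(candidates, start)
    if n_moves > 0 and outside.size == 0:
        raise ValueError("no legal exchange move: candidates == start")
    rng = np.random.default_rng(rng_seed)
    current = start.copy()
    trace: list[tuple[int, float, bool, bool]] = []
    if n_moves == 0:
        return OptimizationResult(current, start.copy(), trace, 0, rng_seed,
                                  criterion_name)
    best = criterion_fn(current)
    if isinstance(best, Rejected):
        trace.append((0, np.nan, False, True))
        best = -np.inf
    else:
        trace.append((0, float(best), True, False))
    for move in range(1, n_moves + 1):
        i = rng.integers(current.size)
        j = rng.integers(outside.size)
        proposal = current.copy()
        proposal[i], swapped_out = outside[j], current[i]
        val = criterion_fn(proposal)
        if isinstance(val, Rejected):
            trace.append((move, np.nan, False, True))
            continue
        val = float(val)
        if val > best:
            current = proposal
            outside[j] = swapped_out
            best = val
            trace.append((move, val, True, False))
        else:
            trace.append((move, val, False, False))
    return OptimizationResult(current, start.copy(), trace, n_moves, rng_seed,
                              criterion_name)


def ethacc_criterion(panel: GenotypePanel, pheno: Phenotype,
                     split: TrainTestSplit, max_qtls: int | None = None,
                     h2_stop: float = 0.01, constraint: bool = True,
                     constraint_tol: float = 1e-12):
    """EthAcc of the current training set, re-estimating everything per set.

    Returns a callable over training index arrays for ``hill_climb``.
    The phenotype must be standardized to unit variance; with
    ``constraint=True`` a set is rejected when the sample variance
    (divisor n_test) of the predicted test genetic values under the
    freshly estimated causal model is >= 1.
    """
    if not pheno.standardized:
        raise ValueError(
            "ethacc_criterion requires a unit-variance phenotype; call "
            "Phenotype.standardize() first")
    y = pheno.values

    def criterion(train_idx: np.ndarray):
        sp = split.with_train(train_idx)
        design = center_design(panel, sp)
        y_tr = y[sp.train_idx]
        vc = reml_variance_components(y_tr, design.Xc_train)
        sub = panel.subset(sp.train_idx)
        causal = mlmm_forward(y_tr, sub, max_qtls=max_qtls, h2_stop=h2_stop)
        if causal.n_qtl == 0:
            return 0.0
        if constraint:
            g_test = causal.genetic_values(panel.dosages[sp.test_idx])
            var_g = float(np.mean((g_test - g_test.mean())**2))
            if var_g >= 1.0 - constraint_tol:
                return Rejected(f"Var(predicted test genetic values)="
                                f"{var_g:.3f} >= 1")
        inputs = EthAccInputs.from_causal_model(design, causal, vc)
        return ethacc(inputs).value

    return criterion


def cdmean_criterion(panel: GenotypePanel, split: TrainTestSplit,
                     vc_panel: VarianceComponents):
    """CDmean with variance components fixed from the whole candidate panel."""

    def criterion(train_idx: np.ndarray):
        return cdmean(panel, split.with_train(train_idx), vc_panel).value

    return criterion


def ts_oracle_criterion(panel: GenotypePanel, pheno: Phenotype,
                        split: TrainTestSplit):
    """Realized test-set accuracy (requires test phenotypes; oracle only)."""
    y = pheno.values
    if np.isnan(y[split.test_idx]).any():
        raise ValueError("test phenotypes unavailable: TS oracle cannot run")

    def criterion(train_idx: np.ndarray):
        sp = split.with_train(train_idx)
        design = center_design(panel, sp)
        y_tr = y[sp.train_idx]
        vc = reml_variance_components(y_tr, design.Xc_train)
        u_hat = gblup_predict(y_tr, design, vc)
        return ts_accuracy(u_hat, y[sp.test_idx]).value

    return criterion
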