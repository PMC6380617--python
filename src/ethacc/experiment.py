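"""Experiment harness: random test-set draws, accuracy-estimator
comparisons, and criterion-driven training-set optimization runs.

The sampling protocol draws a test set (default 20% of the panel) without
replacement; the remaining individuals are the candidate training pool.
Estimates and the realized test-set accuracy are always computed on the
same draw so they are directly comparable, and every random choice is
driven by the run seed recorded in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accuracy import EthAccInputs, cd_accuracy, cdmean, ethacc, pev_accuracy, \
    ts_accuracy
from .gblup import gblup_predict, reml_variance_components
from .optimize import (OptimizationResult, cdmean_criterion, ethacc_criterion,
                       hill_climb, ts_oracle_criterion)
from .panel import GenotypePanel, Phenotype, TrainTestSplit, center_design
from .qtl import mlmm_forward

__all__ = ["ExperimentConfig", "run_experiment", "write_report", "read_report",
           "draw_split", "estimate_all"]

SCHEMA_VERSION = 1


@dataclass
class ExperimentConfig:
    """Sampling protocol and optimization settings for one experiment."""

    ts_fraction: float = 0.20
    n_draws: int = 30
    criteria: list = field(default_factory=lambda: ["cdmean"])
    train_size: int | None = None
    n_moves: int = 5000
    start: str = "random"           # random | ts-oracle
    oracle_moves: int = 500
    constraint: bool = True
    max_qtls: int | None = None
    h2_stop: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ts_fraction < 1:
            raise ValueError("ts_fraction must lie in (0, 1)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.start not in ("random", "ts-oracle"):
            raise ValueError(f"unknown start {self.start!r}")


def draw_split(n_samples: int, ts_fraction: float, rng: np.random.Generator,
               train_size: int | None = None) -> TrainTestSplit:
    """Draw a random test set; the rest is the candidate pool.

    When ``train_size`` is given the initial training set is a random
    subset of the candidates of that size, otherwise the whole pool.
    """
    n_test = max(1, int(round(ts_fraction * n_samples)))
    perm = rng.permutation(n_samples)
    test = np.sort(perm[:n_test])
    cand = np.sort(perm[n_test:])
    if train_size is None:
        train = cand.copy()
    else:
        if train_size > cand.size:
            raise ValueError("train_size exceeds candidate pool")
        train = np.sort(rng.choice(cand, size=train_size, replace=False))
    return TrainTestSplit(train, test, cand)


def estimate_all(panel: GenotypePanel, pheno: Phenotype,
                 split: TrainTestSplit, max_qtls: int | None = None,
                 h2_stop: float = 0.01) -> dict:
    """All accuracy estimates plus the realized TS accuracy on one split."""
    design = center_design(panel, split)
    y = pheno.values
    y_tr = y[split.train_idx]
    vc = reml_variance_components(y_tr, design.Xc_train)
    u_hat = gblup_predict(y_tr, design, vc)
    causal = mlmm_forward(y_tr, panel.subset(split.train_idx),
                          max_qtls=max_qtls, h2_stop=h2_stop)
    eth = ethacc(EthAccInputs.from_causal_model(design, causal, vc))
    return {
        "ts": ts_accuracy(u_hat, y[split.test_idx]).value,
        "cd": cd_accuracy(design, vc).value,
        "pev": pev_accuracy(design, vc).value,
        "ethacc": eth.value,
        "n_qtl": causal.n_qtl,
        "sigma2_beta": vc.sigma2_beta,
        "sigma2_eps": vc.sigma2_eps,
    }


def _build_criterion(name: str, panel, pheno, split, config):
    if name == "ethacc":
        return ethacc_criterion(panel, pheno, split,
                                max_qtls=config.max_qtls,
                                h2_stop=config.h2_stop,
                                constraint=config.constraint)
    if name == "cdmean":
        full = split.with_train(split.candidate_idx)
        d = center_design(panel, full)
        vc_panel = reml_variance_components(pheno.values[full.train_idx],
                                            d.Xc_train)
        return cdmean_criterion(panel, split, vc_panel)
    if name in ("ts_oracle", "ts-oracle"):
        return ts_oracle_criterion(panel, pheno, split)
    raise ValueError(f"unknown criterion {name!r}")


def run_experiment(panel: GenotypePanel, pheno: Phenotype,
                   config: ExperimentConfig) -> dict:
    """Run the draw/estimate/optimize protocol; returns the report dict.

    Per draw: sample a test set and candidate pool, compute all accuracy
    estimates on the full candidate training set, and — when
    ``config.train_size`` is set — hill-climb each requested criterion
    from the configured start and record the final realized TS accuracy.
    Failed draws are recorded with their error and skipped.
    """
    rng = np.random.default_rng(config.seed)
    if any(c == "ethacc" for c in config.criteria) and config.train_size:
        pheno = pheno if pheno.standardized else pheno.standardize()
    rows, failures = [], []
    for draw in range(config.n_draws):
        draw_seed = int(rng.integers(2**31 - 1))
        draw_rng = np.random.default_rng(draw_seed)
        try:
            split = draw_split(panel.n_samples, config.ts_fraction, draw_rng,
                               train_size=config.train_size)
            row = {"draw": draw, "seed": draw_seed,
                   "n_test": int(split.test_idx.size),
                   "n_candidates": int(split.candidate_idx.size)}
            full = split.with_train(split.candidate_idx)
            row.update({f"{k}_full": v for k, v in
                        estimate_all(panel, pheno, full,
                                     max_qtls=config.max_qtls,
                                     h2_stop=config.h2_stop).items()})
            if config.train_size:
                start = split.train_idx
                if config.start == "ts-oracle":
                    res = hill_climb(
                        ts_oracle_criterion(panel, pheno, split),
                        start, split.candidate_idx,
                        n_moves=config.oracle_moves, rng_seed=draw_seed,
                        criterion_name="ts_oracle_start")
                    start = res.final_train_idx
                    row["oracle_start_ts"] = res.best_value
                oracle_fn = ts_oracle_criterion(panel, pheno, split)
                for crit in config.criteria:
                    fn = _build_criterion(crit, panel, pheno, split, config)
                    res = hill_climb(fn, start, split.candidate_idx,
                                     n_moves=config.n_moves,
                                     rng_seed=draw_seed, criterion_name=crit)
                    final_ts = oracle_fn(res.final_train_idx)
                    row[f"{crit}_final_ts"] = float(final_ts)
                    row[f"{crit}_final_criterion"] = res.best_value
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - partial-failure policy
            failures.append({"draw": draw, "seed": draw_seed,
                             "error": f"{type(exc).__name__}: {exc}"})
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                   for k, v in vars(config).items()},
        "n_draws_ok": len(rows),
        "n_draws_failed": len(failures),
        "failures": failures,
    }
    if rows:
        df = pd.DataFrame(rows)
        means = {}
        for col in df.columns:
            if col in ("draw", "seed"):
                continue
            if pd.api.types.is_numeric_dtype(df[col]):
                means[col] = float(df[col].mean())
        summary["means"] = means
        mses = {}
        for est in ("cd", "pev", "ethacc"):
            c = f"{est}_full"
            if c in df:
                mses[est] = float(((df[c] - df["ts_full"])**2).mean())
        summary["mse_vs_ts"] = mses
        summary["per_draw"] = rows
    return summary


def write_report(results: dict, path) -> None:
    """Serialize a report dict to JSON (schema-versioned, sorted keys)."""
    results = dict(results)
    results.setdefault("schema_version", SCHEMA_VERSION)
    if "seed" not in results:
        raise ValueError("report must carry its seed")
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=_to_py)
        fh.write("\n")


def _to_py(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, OptimizationResult):
        return {"final_train_idx": obj.final_train_idx.tolist(),
                "start_train_idx": obj.start_train_idx.tolist(),
                "criterion_trace": [list(t) for t in obj.criterion_trace],
                "n_moves": obj.n_moves, "seed": obj.seed,
                "criterion": obj.criterion}
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_report(path) -> dict:
    """Read a report back, validating the schema essentials."""
    with open(path) as fh:
        data = json.load(fh)
    for key in ("schema_version", "seed"):
        if key not in data:
            raise ValueError(f"report missing required field {key!r}")
    return data
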