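"""The accuracy estimators: TS, CD, PEV, EthAcc and CDmean."""

import numpy as np
import pytest
from scipy import linalg

from ethacc.accuracy import (EthAccInputs, cd_accuracy, cdmean, ethacc,
                             pev_accuracy, ts_accuracy)
from ethacc.gblup import (VarianceComponents, reml_variance_components,
                          ridge_matrix)
from ethacc.panel import (CenteredDesign, GenotypePanel, TrainTestSplit,
                          center_design)
from ethacc.qtl import CausalModel, fit_causal_ols
from ethacc.simulate import SimConfig, simulate_genotypes, simulate_phenotype

from conftest import random_design, random_split


class TestTSAccuracy:
    def test_perfect_and_anti_correlation(self):
        y = np.array([0.3, 1.2, -0.5, 2.0])
        assert ts_accuracy(y, y).value == pytest.approx(1.0)
        assert ts_accuracy(-y, y).value == pytest.approx(-1.0)

    def test_matches_from_definition_formula(self):
        y = np.array([1.0, 2.0, 3.0, 5.0])
        u = np.array([1.0, 1.0, 2.0, 4.0])
        yc, uc = y - y.mean(), u - u.mean()
        expected = (yc @ uc) / np.sqrt((yc @ yc) * (uc @ uc))
        assert ts_accuracy(u, y).value == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ts_accuracy(np.ones(5), np.arange(5.0))


class TestCDAndPEV:
    def test_zero_test_genotype_contributes_zero(self):
        rng = np.random.default_rng(0)
        Xc = rng.standard_normal((10, 5))
        Xc -= Xc.mean(axis=0)
        design = CenteredDesign(Xc, np.zeros((1, 5)), np.zeros(5))
        vc = VarianceComponents(1.0, 1.0)
        with pytest.warns(UserWarning, match="training mean"):
            est = cd_accuracy(design, vc)
        assert est.value == 0.0

    def test_training_row_cd_approaches_one_at_small_lambda(self):
        # full-rank-T design, test individual equals a training row
        rng = np.random.default_rng(1)
        Xc = rng.standard_normal((8, 30))
        Xc -= Xc.mean(axis=0)
        design = CenteredDesign(Xc, Xc[[2]], np.zeros(30))
        vc = VarianceComponents(sigma2_beta=1.0, sigma2_eps=1e-10)
        cd_i = cd_accuracy(design, vc).per_test
        assert cd_i[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_monte_carlo_under_gblup_generative_model(self):
        """CD's per-test term equals sqrt(h_i^2)*corr(g_i, ghat_i) under the
        marker model, estimated over replicate draws of beta and eps."""
        rng = np.random.default_rng(5)
        Xc = rng.standard_normal((30, 50))
        Xc -= Xc.mean(axis=0)
        Xt = rng.standard_normal((6, 50))
        design = CenteredDesign(Xc, Xt, np.zeros(50))
        s2b, s2e = 0.01, 0.5
        vc = VarianceComponents(s2b, s2e)
        est = cd_accuracy(design, vc)

        H = ridge_matrix(Xc, vc)
        P = Xt @ Xc.T @ linalg.inv(H)
        n_rep = 5000
        beta = rng.normal(0, np.sqrt(s2b), size=(50, n_rep))
        eps = rng.normal(0, np.sqrt(s2e), size=(30, n_rep))
        g = Xt @ beta                       # true genetic values
        ghat = P @ (Xc @ beta + eps)
        gm, gh = g - g.mean(1, keepdims=True), ghat - ghat.mean(1, keepdims=True)
        corr = np.sum(gm * gh, axis=1) / np.sqrt(
            np.sum(gm**2, axis=1) * np.sum(gh**2, axis=1))
        xx = np.sum(Xt**2, axis=1)
        h2 = s2b * xx / (s2b * xx + s2e)
        mc = np.mean(np.sqrt(h2) * corr)
        # MC standard error of the mean of per-test sqrt(h2)*corr
        se = np.std(np.sqrt(h2) * corr) / np.sqrt(6) / np.sqrt(n_rep) * 30
        assert est.value == pytest.approx(mc, abs=max(3 * se, 0.02))

    def test_unrelated_test_pev_equals_var(self):
        # test genotype orthogonal to every training row -> zero information
        Xc = np.zeros((4, 3))
        Xc[:2, 0], Xc[2:, 0] = 1.0, -1.0
        x = np.array([[0.0, 1.0, 0.0]])
        design = CenteredDesign(Xc, x, np.zeros(3))
        vc = VarianceComponents(2.0, 1.0)
        est = pev_accuracy(design, vc)
        assert est.per_test[0] == pytest.approx(2.0)   # = sigma2_beta*x'x
        assert est.value == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_cd_equals_pev_identity(self, seed):
        panel, pheno, _, split, design = random_design(seed)
        vc = reml_variance_components(pheno.values[split.train_idx],
                                      design.Xc_train)
        assert cd_accuracy(design, vc).value == pytest.approx(
            pev_accuracy(design, vc).value, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_pev_nonnegative(self, seed):
        panel, pheno, _, split, design = random_design(seed + 50)
        vc = reml_variance_components(pheno.values[split.train_idx],
                                      design.Xc_train)
        assert (pev_accuracy(design, vc).per_test >= -1e-10).all()


def _true_causal_inputs(panel, truth, split, design, vc):
    cm = CausalModel(truth.qtl_indices, truth.theta_true, 0.0,
                     truth.sigma2_e)
    return EthAccInputs.from_causal_model(design, cm, vc)


class TestEthAcc:
    def test_null_effects_give_zero(self):
        panel, pheno, truth, split, design = random_design(2)
        vc = VarianceComponents(1.0, 1.0)
        cm = CausalModel(truth.qtl_indices,
                         np.zeros_like(truth.theta_true), 0.0, 1.0)
        est = ethacc(EthAccInputs.from_causal_model(design, cm, vc))
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_empty_causal_model_is_zero_with_warning(self):
        panel, pheno, truth, split, design = random_design(3)
        vc = VarianceComponents(1.0, 1.0)
        cm = CausalModel(np.array([], int), np.array([]), 0.0, 1.0)
        with pytest.warns(UserWarning, match="empty causal model"):
            est = ethacc(EthAccInputs.from_causal_model(design, cm, vc))
        assert est.value == 0.0

    def test_self_prediction_limit_approaches_one(self):
        # single observed QTL, test set = training set, tiny lambda and
        # tiny causal noise: the formula must approach 1
        rng = np.random.default_rng(4)
        X = rng.binomial(2, 0.5, size=(12, 6)).astype(float)
        panel = GenotypePanel(X, [f"s{i}" for i in range(12)],
                              [f"m{j}" for j in range(6)])
        Xc = X - X.mean(axis=0)
        design = CenteredDesign(Xc, Xc, X.mean(axis=0))
        vc = VarianceComponents(sigma2_beta=1.0, sigma2_eps=1e-9)
        cm = CausalModel(np.array([0]), np.array([1.5]), 0.0, 1e-12)
        est = ethacc(EthAccInputs.from_causal_model(design, cm, vc))
        assert est.value == pytest.approx(1.0, abs=1e-3)

    def test_matches_monte_carlo_accuracy_with_true_model(self):
        """The theoretical formula tracks realized accuracy when the causal
        model is known (moderate size; the full-size run is in the
        acceptance suite)."""
        cfg = SimConfig(n_samples=180, n_markers=250, n_clusters=1, fst=0.2,
                        inbred=True, seed=21)
        panel = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotype(panel, n_qtl=8, h2=0.5, seed=22)
        split = random_split(180, 36, 23)
        design = center_design(panel, split)
        vc = reml_variance_components(pheno.values[split.train_idx],
                                      design.Xc_train)
        est = ethacc(_true_causal_inputs(panel, truth, split, design, vc))

        H = ridge_matrix(design.Xc_train, vc)
        P = design.Xc_test @ design.Xc_train.T @ linalg.inv(H)
        g_tr = truth.genetic_values[split.train_idx]
        g_te = truth.genetic_values[split.test_idx]
        rng = np.random.default_rng(24)
        sd = np.sqrt(truth.sigma2_e)
        cors = []
        for _ in range(400):
            y_tr = g_tr + rng.standard_normal(g_tr.size) * sd
            y_te = g_te + rng.standard_normal(g_te.size) * sd
            u = P @ (y_tr - y_tr.mean())
            cors.append(np.corrcoef(y_te, u)[0, 1])
        assert est.value == pytest.approx(np.mean(cors), abs=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_bounded_by_one(self, seed):
        panel, pheno, truth, split, design = random_design(seed + 100)
        vc = reml_variance_components(pheno.values[split.train_idx],
                                      design.Xc_train)
        est = ethacc(_true_causal_inputs(panel, truth, split, design, vc))
        assert abs(est.value) <= 1 + 1e-8

    def test_components_reported(self):
        panel, pheno, truth, split, design = random_design(6)
        vc = VarianceComponents(1.0, 1.0)
        est = ethacc(_true_causal_inputs(panel, truth, split, design, vc))
        for key in ("numerator", "noise_term", "signal_dispersion_term",
                    "sigma2_g", "sigma2_e"):
            assert key in est.components


class TestCDmean:
    def test_all_candidates_full_information_limit(self):
        # training = all candidates, tiny lambda, full-rank design
        rng = np.random.default_rng(31)
        X = rng.standard_normal((10, 40))
        panel = GenotypePanel(X, [f"s{i}" for i in range(10)],
                              [f"m{j}" for j in range(40)])
        split = TrainTestSplit(np.arange(7), np.arange(7, 10))
        vc = VarianceComponents(sigma2_beta=1.0, sigma2_eps=1e-10)
        est = cdmean(panel, split, vc)
        # the contrast between a *test* individual and the mean is never
        # fully determined by training data alone, but CD values must be
        # valid and high information keeps them in [0, 1]
        assert np.all(est.per_test >= 0) and np.all(est.per_test <= 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_cd_of_contrasts_within_unit_interval(self, seed):
        panel, pheno, _, split, _ = random_design(seed + 200, T=15,
                                                  n_test=5, M=25)
        vc = reml_variance_components(pheno.values[split.train_idx],
                                      center_design(panel, split).Xc_train)
        est = cdmean(panel, split, vc)
        assert np.all(est.per_test >= 0) and np.all(est.per_test <= 1)

    def test_monte_carlo_covariance_oracle(self):
        """CD(c) == Cov(c'uhat, c'u) / Var(c'u) estimated by simulating the
        GBLUP generative model on a tiny instance (N=8, M=12)."""
        rng = np.random.default_rng(32)
        X = rng.binomial(2, 0.5, size=(8, 12)).astype(float)
        panel = GenotypePanel(X, [f"s{i}" for i in range(8)],
                              [f"m{j}" for j in range(12)])
        split = TrainTestSplit(np.arange(5), np.arange(5, 8))
        s2b, s2e = 0.5, 1.0
        vc = VarianceComponents(s2b, s2e)
        est = cdmean(panel, split, vc)

        all_idx = np.concatenate([split.train_idx, split.test_idx])
        X_all = X[all_idx]
        Xc_all = X_all - X_all.mean(axis=0)
        Xc_tr = Xc_all[:5]
        H = ridge_matrix(Xc_tr, vc)
        W = Xc_all @ Xc_tr.T @ linalg.inv(H)
        n_rep = 200_000
        beta = rng.normal(0, np.sqrt(s2b), size=(12, n_rep))
        eps = rng.normal(0, np.sqrt(s2e), size=(5, n_rep))
        u = Xc_all @ beta
        uhat = W @ (Xc_tr @ beta + eps)
        for k in range(3):
            c = -np.full(8, 1 / 8)
            c[5 + k] += 1
            cu, cuh = c @ u, c @ uhat
            cov = np.mean(cu * cuh) - cu.mean() * cuh.mean()
            var = np.var(cu)
            assert est.per_test[k] == pytest.approx(cov / var, abs=0.02)

    def test_rescaling_invariance(self):
        panel, pheno, _, split, _ = random_design(33, T=15, n_test=5, M=25)
        vc = VarianceComponents(1.0, 3.0)
        base = cdmean(panel, split, vc).value
        scaled_panel = GenotypePanel(panel.dosages * 2.0, panel.sample_ids,
                                     panel.marker_ids)
        # lambda in H scales with the squared coding factor
        vc_scaled = VarianceComponents(1.0, 3.0 * 4.0)
        assert cdmean(scaled_panel, split, vc_scaled).value == \
            pytest.approx(base, abs=1e-10)
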