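"""Node-wise LASSO estimation and network assembly."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pytest

from clpnet import (EstimationConfig, SimulationConfig, TrueNetworkSpec,
                    build_network, dichotomize, fit_node, generate_true_network,
                    simulate_panel)
from clpnet.estimate import _fit_l1_logistic, zero_variance_columns
from clpnet.panel import N_NODES


class TestDichotomize:
    def test_all_zeros_stay_zero(self):
        assert np.all(dichotomize(np.zeros((5, 3))) == 0)

    def test_threshold_boundaries(self):
        items = np.array([[0, 1, 2, 3]], dtype=float)
        assert dichotomize(items, 0).tolist() == [[0, 1, 1, 1]]
        assert dichotomize(items, 1).tolist() == [[0, 0, 1, 1]]
        assert dichotomize(items, 2).tolist() == [[0, 0, 0, 1]]

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="imputed"):
            dichotomize(np.array([[np.nan, 1.0]]))

    def test_constant_column_flagged(self):
        binary = np.array([[1, 0], [1, 1], [1, 0]], dtype=float)
        assert zero_variance_columns(binary).tolist() == [0]


class TestFitNode:
    def test_huge_lambda_shrinks_everything_to_zero(self, rng):
        n = 300
        X = (rng.random((n, N_NODES)) < 0.4).astype(float)
        y = (rng.random(n) < 0.5).astype(float)
        _, beta = _fit_l1_logistic(X, y, lam=10.0)
        assert np.all(beta == 0)

    def test_single_class_target_returns_degenerate_zero_fit(self, rng):
        X = (rng.random((100, N_NODES)) < 0.4).astype(float)
        fit = fit_node(np.zeros(100), X, np.zeros((100, 1)), EstimationConfig())
        assert fit.degenerate
        assert np.all(fit.coef == 0)

    def test_single_edge_recovery_with_min_rule(self):
        """True coefficient 1.0 on one cross path: the CV-min fit lands
        within +-0.3 and selects the edge in >= 9 of 10 seeds."""
        hits, close = 0, 0
        for seed in range(10):
            spec = TrueNetworkSpec()
            spec.cross_coef[6, 0] = 1.0  # D7 -> D1
            panel = simulate_panel(spec, SimulationConfig(n_participants=5000, seed=seed))
            net = build_network(panel, EstimationConfig(seed=seed + 100, lambda_rule="min"))
            c = net.coef[6, 0]
            hits += c != 0
            close += abs(c - 1.0) <= 0.3
        assert hits >= 9
        assert close >= 9

    def test_permuted_target_selects_nothing(self, clean_panel):
        """Permuting the wave-2 target destroys the signal: the median count
        of selected cross-lagged predictors over permutations is 0."""
        rng = np.random.default_rng(0)
        X1 = dichotomize(clean_panel.wave1_items)
        X2 = dichotomize(clean_panel.wave2_items)
        cov = np.column_stack([(clean_panel.age - clean_panel.age.mean()),
                               clean_panel.gender.astype(float)])
        counts = []
        for k in range(10):
            y = rng.permutation(X2[:, 0])
            fit = fit_node(y, X1, cov, EstimationConfig(seed=k))
            counts.append(np.count_nonzero(np.delete(fit.coef, 0)))
        assert np.median(counts) == 0

    def test_matches_glmnet_at_fixed_lambda(self, rng):
        """Independent oracle: glmnet (R) with penalty.factor zero on the
        covariates reproduces the penalized fit at a fixed lambda."""
        n = 600
        spec = generate_true_network(8, effect_range=(0.6, 0.9), seed=3,
                                     positive_only=True)
        panel = simulate_panel(spec, SimulationConfig(n_participants=n, seed=4))
        X1 = dichotomize(panel.wave1_items)
        y = dichotomize(panel.wave2_items)[:, 0]
        age_z = (panel.age - panel.age.mean()) / panel.age.std()
        cov = np.column_stack([age_z, panel.gender.astype(float)])
        lam = 0.02
        X = np.hstack([X1, cov])
        pf = np.concatenate([np.ones(N_NODES), np.zeros(2)])
        _, beta = _fit_l1_logistic(X, y, lam, penalty_factor=pf)
        beta_ours = beta[:N_NODES]

        with tempfile.TemporaryDirectory() as td:
            td = Path(td)
            np.savetxt(td / "X.csv", np.hstack([X1, cov]), delimiter=",")
            np.savetxt(td / "y.csv", y, delimiter=",")
            nvars = N_NODES + 2
            # glmnet rescales penalty factors to sum to nvars; compensate
            lam_glmnet = lam * N_NODES / nvars
            script = f"""
            suppressMessages(library(glmnet))
            X <- as.matrix(read.csv("{td}/X.csv", header=FALSE))
            y <- scan("{td}/y.csv", quiet=TRUE)
            pf <- c(rep(1, {N_NODES}), rep(0, 2))
            fit <- glmnet(X, y, family="binomial", alpha=1, lambda={lam_glmnet},
                          penalty.factor=pf, standardize=FALSE, thresh=1e-12)
            write.csv(as.matrix(coef(fit)), "{td}/beta.csv")
            """
            (td / "fit.R").write_text(script)
            subprocess.run(["Rscript", str(td / "fit.R")], check=True,
                           capture_output=True)
            beta_r = np.genfromtxt(td / "beta.csv", delimiter=",", skip_header=1,
                                   usecols=1)
        beta_glmnet = beta_r[1:1 + N_NODES]
        assert np.allclose(beta_ours, beta_glmnet, atol=0.03)
        # same support up to boundary wobble
        disagree = np.sum((beta_ours != 0) != (np.abs(beta_glmnet) > 1e-8))
        assert disagree <= 2


class TestBuildNetwork:
    def test_determinism_under_seed(self, clean_panel):
        a = build_network(clean_panel, EstimationConfig(seed=5))
        b = build_network(clean_panel, EstimationConfig(seed=5))
        assert np.array_equal(a.coef, b.coef)
        assert np.array_equal(a.auto, b.auto)

    def test_or_coef_duality(self, fitted_network):
        assert np.allclose(fitted_network.or_matrix, np.exp(fitted_network.coef))
        absent = fitted_network.coef == 0
        assert np.all(fitted_network.or_matrix[absent] == 1.0)

    def test_diagonal_held_in_auto(self, fitted_network):
        assert np.all(np.diag(fitted_network.coef) == 0)
        assert np.count_nonzero(fitted_network.auto) > 0  # persistence is strong

    def test_small_sample_rejected(self, sparse_spec):
        panel = simulate_panel(sparse_spec, SimulationConfig(n_participants=36, seed=1))
        with pytest.raises(ValueError, match="sample size"):
            build_network(panel)

    def test_missing_values_rejected(self, sparse_spec):
        panel = simulate_panel(sparse_spec, SimulationConfig(
            n_participants=100, missing_rate=0.05, seed=2))
        with pytest.raises(ValueError, match="impute"):
            build_network(panel)

    def test_shrinkage_monotone_along_path(self, clean_panel):
        """Forcing ever larger penalties never grows the selected support."""
        X1 = dichotomize(clean_panel.wave1_items)
        y = dichotomize(clean_panel.wave2_items)[:, 2]
        counts = []
        for lam in np.geomspace(0.5, 0.001, 8):
            _, beta = _fit_l1_logistic(X1, y, lam)
            counts.append(np.count_nonzero(beta))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_edge_table_round_trip(self, fitted_network, tmp_path):
        edges = fitted_network.edges()
        assert set(edges["edge_type"]) <= {"cross_lagged", "autoregressive"}
        assert np.allclose(edges["odds_ratio"], np.exp(edges["coef"]))
        fitted_network.to_graphml(tmp_path / "net.graphml")
        import networkx as nx
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_edges() == len(edges)

    def test_gaussian_family_runs(self, clean_panel):
        net = build_network(clean_panel, EstimationConfig(seed=1, family="gaussian"))
        assert net.family == "gaussian"
        assert np.count_nonzero(net.coef) > 0
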