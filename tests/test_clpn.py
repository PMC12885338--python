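import numpy as np
import pandas as pd
import pytest

import panelnet as pn
from panelnet.clpn import (build_lagged_design, cv_lasso, directed_expected_influence,
                           fit_clpn, LaggedDesign)
from panelnet.ggm import EstimationError


def _no_attrition_panel(n0, seed, truth=None):
    truth = truth or pn.default_ground_truth(attrition_intercept=-np.inf)
    return pn.simulate_panel(truth, n0=n0, waves=2, seed=seed)


class TestBuildLaggedDesign:
    def test_no_attrition_full_n(self):
        panel = _no_attrition_panel(100, 0)
        for outcome in panel.node_labels:
            d = build_lagged_design(panel, "T0", "T1", outcome)
            assert d.n_complete == 100
            assert list(d.X.columns) == panel.node_labels + panel.covariate_labels

    def test_listwise_exclusion(self):
        panel = _no_attrition_panel(100, 1)
        pid = panel.data["participant_id"].iloc[0]
        mask = (panel.data["participant_id"] == pid) & (panel.data["wave"] == "T1")
        panel.data.loc[mask, "SQQ"] = np.nan  # one symptom missing at to_wave
        for outcome in ("DEP", "SQQ"):
            d = build_lagged_design(panel, "T0", "T1", outcome)
            assert d.n_complete == 99
            assert pid not in d.X.index

    def test_attrition_count_consistent_across_outcomes(self, cohort_panel):
        counts = {o: build_lagged_design(cohort_panel, "T0", "T1", o).n_complete
                  for o in cohort_panel.node_labels}
        assert len(set(counts.values())) == 1
        assert counts["DEP"] == cohort_panel.n_per_wave()["T1"]

    def test_too_few_cases(self):
        panel = _no_attrition_panel(100, 2)
        panel.data = panel.data[panel.data["participant_id"]
                                .isin(panel.data["participant_id"].unique()[:12])]
        with pytest.raises(EstimationError):
            build_lagged_design(panel, "T0", "T1", "DEP")


def _synthetic_design(n, beta, seed, n_noise=8):
    """Direct design with one known coefficient vector for recovery tests."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, n_noise + 1)),
                     columns=[f"x{i}" for i in range(n_noise + 1)])
    y = pd.Series(X.to_numpy() @ beta + rng.standard_normal(n), name="y")
    return LaggedDesign(X=X, y=y, outcome_label="y", n_complete=n,
                        penalized=list(X.columns))


class TestCvLasso:
    def test_lambda_1se_geq_lambda_min(self):
        for seed in range(5):
            d = _synthetic_design(200, np.r_[0.5, np.zeros(8)], seed)
            fit = cv_lasso(d, penalty_free=[], seed=seed)
            assert fit.path.lambda_1se >= fit.path.lambda_min

    def test_1se_definition_reproducible_from_path(self):
        d = _synthetic_design(300, np.r_[0.4, np.zeros(8)], 3)
        fit = cv_lasso(d, penalty_free=[], seed=3)
        path = fit.path
        i_min = int(np.argmin(path.cv_mean))
        thr = path.cv_mean[i_min] + path.cv_se[i_min]
        eligible = path.lambda_grid[path.cv_mean <= thr]
        assert path.lambda_1se == pytest.approx(float(eligible.max()))

    def test_null_model_all_zero(self):
        """Pure-noise outcome: every penalized coefficient is 0 at λ.1se in
        the vast majority of seeds."""
        hits = 0
        for seed in range(20):
            d = _synthetic_design(500, np.zeros(9), seed)
            fit = cv_lasso(d, penalty_free=[], seed=seed)
            hits += np.all(fit.coef.to_numpy() == 0.0)
        assert hits >= 18

    def test_single_predictor_recovered(self):
        hits = 0
        for seed in range(20):
            d = _synthetic_design(500, np.r_[0.6, np.zeros(8)], seed)
            fit = cv_lasso(d, penalty_free=[], seed=seed)
            hits += fit.coef.iloc[0] > 0 and np.count_nonzero(fit.coef.iloc[1:]) == 0
        assert hits >= 18

    def test_sparsity_monotone_lambda_min_vs_1se(self):
        for seed in range(5):
            d = _synthetic_design(300, np.r_[0.5, 0.3, np.zeros(7)], seed)
            fit = cv_lasso(d, penalty_free=[], seed=seed)
            assert (np.count_nonzero(fit.coef_at_lambda_min)
                    >= np.count_nonzero(fit.coef))

    def test_penalty_free_covariate_always_retained(self):
        rng = np.random.default_rng(11)
        n = 300
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["x0", "x1", "age"])
        y = pd.Series(0.05 * X["age"].to_numpy() + rng.standard_normal(n))
        d = LaggedDesign(X=X, y=y, outcome_label="y", n_complete=n,
                         penalized=["x0", "x1"])
        fit = cv_lasso(d, penalty_free=["age"], seed=0)
        assert "age" in fit.covariate_coef.index
        # partialling-out equivalence: covariate coefficient is the OLS coefficient
        # of the residual y − X·β on [1, age]
        Z = np.column_stack([np.ones(n), X["age"]])
        resid = y.to_numpy() - X[["x0", "x1"]].to_numpy() @ fit.coef[["x0", "x1"]].to_numpy()
        alpha = np.linalg.lstsq(Z, resid, rcond=None)[0]
        assert fit.covariate_coef["age"] == pytest.approx(alpha[1], abs=1e-10)


class TestFitClpn:
    def test_row_permutation_invariance(self):
        panel = _no_attrition_panel(150, 4)
        net1 = fit_clpn(panel, "T0", "T1", seed=5, n_lambda=30)
        shuffled = panel.copy()
        rng = np.random.default_rng(0)
        shuffled.data = shuffled.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        net2 = fit_clpn(pn.PanelDataset(shuffled.data), "T0", "T1", seed=5, n_lambda=30)
        np.testing.assert_array_equal(net1.A, net2.A)

    def test_seed_determinism(self):
        panel = _no_attrition_panel(150, 6)
        a1 = fit_clpn(panel, "T0", "T1", seed=9, n_lambda=30).A
        a2 = fit_clpn(panel, "T0", "T1", seed=9, n_lambda=30).A
        np.testing.assert_array_equal(a1, a2)

    def test_null_transition_large_n(self):
        """With a zero transition matrix the selected lagged network is
        (nearly) empty at large n — majority over seeds."""
        truth = pn.make_ground_truth([("SuI", "SuT", 0.3)], [], autoregressive=0.0,
                                     attrition_intercept=-np.inf)
        empties = 0
        for seed in range(6):
            panel = pn.simulate_panel(truth, n0=2000, waves=2, seed=seed)
            net = fit_clpn(panel, "T0", "T1", seed=seed, n_lambda=40)
            empties += np.count_nonzero(net.A) <= 2
        assert empties >= 4

    def test_path_recovery(self, default_truth):
        """The three largest cross-lagged coefficients identify the three true
        ordered paths (single-seed version of the larger simulation)."""
        truth = pn.default_ground_truth(attrition_intercept=-np.inf)
        panel = pn.simulate_panel(truth, n0=500, waves=2, seed=42)
        net = fit_clpn(panel, "T0", "T1", seed=42)
        off = net.A - np.diag(np.diag(net.A))
        order = np.argsort(-np.abs(off).ravel())[:3]
        found = {(net.labels[i], net.labels[j])
                 for i, j in zip(*np.unravel_index(order, off.shape))}
        assert found == {("AcS", "SOM"), ("AcS", "DEP"), ("SuI", "SuT")}


class TestDirectedExpectedInfluence:
    def test_small_example_diagonal_ignored(self):
        A = np.zeros((3, 3))
        A[0, 1], A[1, 0], A[0, 0] = 0.5, 0.2, 0.3
        net = pn.DirectedNetwork(A=A, covariate_coefs=np.zeros((4, 3)),
                                 wave_pair=("T0", "T1"), n_per_outcome={},
                                 labels=["a", "b", "c"])
        dc = directed_expected_influence(net)
        np.testing.assert_allclose(dc.table["out_EI"], [0.5, 0.2, 0.0])
        np.testing.assert_allclose(dc.table["in_EI"], [0.2, 0.5, 0.0])
        assert dc.k == 2

    def test_zero_matrix(self):
        net = pn.DirectedNetwork(A=np.zeros((4, 4)), covariate_coefs=np.zeros((4, 4)),
                                 wave_pair=("T0", "T1"), n_per_outcome={},
                                 labels=list("abcd"))
        dc = directed_expected_influence(net)
        assert np.all(dc.table.to_numpy() == 0.0)

    def test_summation_oracle_and_conservation(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((9, 9)) * 0.2
        net = pn.DirectedNetwork(A=A, covariate_coefs=np.zeros((4, 9)),
                                 wave_pair=("T0", "T1"), n_per_outcome={},
                                 labels=[f"v{i}" for i in range(9)])
        dc = directed_expected_influence(net)
        for i in range(9):
            assert dc.table["out_EI"].iloc[i] == pytest.approx(
                sum(A[i, j] for j in range(9) if j != i))
            assert dc.table["in_EI"].iloc[i] == pytest.approx(
                sum(A[j, i] for j in range(9) if j != i))
        off_sum = A.sum() - np.trace(A)
        assert dc.table["in_EI"].sum() == pytest.approx(off_sum)
        assert dc.table["out_EI"].sum() == pytest.approx(off_sum)
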