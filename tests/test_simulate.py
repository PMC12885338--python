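import io

import numpy as np
import pytest

import panelnet as pn
from panelnet.simulate import ConstructionError


class TestMakeGroundTruth:
    def test_identity_case(self):
        truth = pn.make_ground_truth([], [], autoregressive=0.0)
        np.testing.assert_array_equal(truth.precision_resid, np.eye(9))
        np.testing.assert_array_equal(truth.transition, np.zeros((9, 9)))

    def test_single_partial_is_exact(self):
        truth = pn.make_ground_truth([("SuI", "SuT", 0.4)], [])
        P = truth.implied_partials()
        i, j = truth.node_labels.index("SuI"), truth.node_labels.index("SuT")
        assert P[i, j] == pytest.approx(0.4, abs=1e-8)
        mask = np.ones_like(P, bool)
        mask[i, j] = mask[j, i] = False
        np.fill_diagonal(mask, False)
        assert np.all(np.abs(P[mask]) < 1e-8)

    def test_inversion_oracle(self):
        """Implied partials recomputed via an independent covariance round-trip."""
        truth = pn.default_ground_truth()
        Sigma = np.linalg.inv(truth.precision_resid)
        K2 = np.linalg.inv(Sigma)
        d = np.sqrt(np.diag(K2))
        P2 = -K2 / np.outer(d, d)
        np.fill_diagonal(P2, 0.0)
        np.testing.assert_allclose(P2, truth.implied_partials(), atol=1e-10)

    def test_transition_layout_and_stability(self):
        truth = pn.make_ground_truth(
            [], [("AcS", "SOM", 0.4), ("AcS", "DEP", 0.35), ("SuI", "SuT", 0.4)],
            autoregressive=0.3)
        B = truth.transition
        labs = truth.node_labels
        assert B[labs.index("AcS"), labs.index("SOM")] == 0.4
        assert np.all(np.diag(B) == 0.3)
        assert np.max(np.abs(np.linalg.eigvals(B))) < 1.0

    def test_non_positive_definite_request_names_spectrum(self):
        with pytest.raises(ConstructionError, match="eigenvalues"):
            pn.make_ground_truth(
                [("DEP", "SOM", 0.9), ("DEP", "ANX", 0.9), ("SOM", "ANX", 0.9)], [])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ConstructionError, match="duplicate"):
            pn.make_ground_truth([("DEP", "SOM", 0.2), ("SOM", "DEP", 0.3)], [])

    def test_unstable_transition_rejected(self):
        with pytest.raises(ConstructionError, match="spectral radius"):
            pn.make_ground_truth([], [], autoregressive=1.05)


class TestSimulatePanel:
    def test_no_dropout_when_intercept_minus_inf(self, default_truth):
        truth = pn.default_ground_truth(attrition_intercept=-np.inf)
        panel = pn.simulate_panel(truth, n0=50, waves=3, seed=0)
        assert panel.n_per_wave() == {"T0": 50, "T1": 50, "T2": 50}

    def test_reproducible_byte_identical(self, default_truth):
        bufs = []
        for _ in range(2):
            panel = pn.simulate_panel(default_truth, n0=80, waves=3, seed=42)
            buf = io.StringIO()
            panel.to_csv(buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_monotone_missingness(self, cohort_panel):
        wide = cohort_panel.wide()
        m1 = wide["DEP_T1"].isna()
        m2 = wide["DEP_T2"].isna()
        assert (m2 | ~m1).all()  # missing at T1 implies missing at T2

    def test_completers_less_severe_at_baseline(self, default_truth):
        panel = pn.simulate_panel(default_truth, n0=4000, waves=2, seed=7)
        wide = panel.wide()
        completer = wide["DEP_T1"].notna()
        assert wide.loc[completer, "DEP_T0"].mean() < wide.loc[~completer, "DEP_T0"].mean()

    def test_moment_recovery_wave0(self, default_truth):
        """Sample covariance of wave-0 scores matches inv(precision) within 3 SE."""
        n0 = 10_000
        panel = pn.simulate_panel(default_truth, n0=n0, waves=2, seed=3)
        X = panel.complete_cases("T0").to_numpy()
        S = np.cov(X, rowvar=False)
        Sigma = default_truth.residual_covariance()
        se = np.sqrt((np.outer(np.diag(Sigma), np.diag(Sigma)) + Sigma ** 2) / n0)
        assert np.all(np.abs(S - Sigma) < 3.5 * se)

    def test_iid_waves_without_transition(self):
        truth = pn.make_ground_truth([("SuI", "SuT", 0.4)], [], autoregressive=0.0,
                                     attrition_intercept=-np.inf)
        panel = pn.simulate_panel(truth, n0=20_000, waves=2, seed=9)
        x0 = panel.complete_cases("T0").to_numpy()
        x1 = panel.complete_cases("T1").to_numpy()
        cross = np.array([[np.corrcoef(x0[:, i], x1[:, j])[0, 1]
                           for j in range(9)] for i in range(9)])
        assert np.max(np.abs(cross)) < 0.03

    def test_sample_partial_matches_requested(self):
        truth = pn.make_ground_truth([("SuI", "SuT", 0.4)], [],
                                     attrition_intercept=-np.inf)
        panel = pn.simulate_panel(truth, n0=20_000, waves=2, seed=13)
        X = panel.complete_cases("T0").to_numpy()
        K = np.linalg.inv(np.cov(X, rowvar=False))
        d = np.sqrt(np.diag(K))
        P = -K / np.outer(d, d)
        i, j = truth.node_labels.index("SuI"), truth.node_labels.index("SuT")
        assert P[i, j] == pytest.approx(0.4, abs=0.02)

    def test_attrition_monotone_in_slope(self):
        """A steeper severity slope reduces first-follow-up completers on
        average.  (Checked as a mean over seeds: pointwise monotonicity fails
        for below-average-severity participants, whose dropout probability
        falls as the slope rises.  At the second follow-up the property need
        not hold at all — severity-selective dropout at T1 leaves a
        low-severity pool whose T2 retention is higher, and the positive
        covariance between the two survival events can outweigh the marginal
        increase in dropout.)"""
        means = []
        for slope in (0.0, 0.8):
            truth = pn.default_ground_truth(attrition_slope=slope)
            counts = [pn.simulate_panel(truth, n0=400, waves=3, seed=s).n_per_wave()["T1"]
                      for s in range(30)]
            means.append(np.mean(counts))
        assert means[0] > means[1]

    def test_precondition_failures(self, default_truth):
        with pytest.raises(ValueError):
            pn.simulate_panel(default_truth, n0=5, waves=3, seed=0)
        with pytest.raises(ValueError):
            pn.simulate_panel(default_truth, n0=50, waves=4, seed=0)

    def test_stationary_init_keeps_marginals_constant(self):
        truth = pn.default_ground_truth(attrition_intercept=-np.inf)
        panel = pn.simulate_panel(truth, n0=20_000, waves=3, seed=2,
                                  stationary_init=True)
        v0 = panel.complete_cases("T0").var().to_numpy()
        v2 = panel.complete_cases("T2").var().to_numpy()
        assert np.allclose(v0, v2, rtol=0.12)
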