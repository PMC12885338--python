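import numpy as np
import pytest

import panelnet as pn


@pytest.fixture(scope="session")
def toy3_W():
    """3-node toy: w_AB = 0.5, w_AC = 0.25, w_BC = 0."""
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    W[0, 2] = W[2, 0] = 0.25
    return W


@pytest.fixture(scope="session")
def default_truth():
    return pn.default_ground_truth(seed=0)


@pytest.fixture(scope="session")
def cohort_panel(default_truth):
    """Cohort-scale three-wave panel with attrition (session-cached)."""
    return pn.simulate_panel(default_truth, n0=650, waves=3, seed=11)


@pytest.fixture(scope="session")
def small_panel(default_truth):
    """Small two-wave panel without dropout, for fast estimator tests."""
    truth = pn.default_ground_truth(seed=0, attrition_intercept=-np.inf)
    return pn.simulate_panel(truth, n0=120, waves=2, seed=5)


def random_edge_matrix(rng, n, density=0.6, signed=True):
    """Random symmetric zero-diagonal edge matrix."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < density:
                w = rng.uniform(0.05, 0.9)
                if signed and rng.uniform() < 0.3:
                    w = -w
                W[i, j] = W[j, i] = w
    return W
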