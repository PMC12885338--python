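"""Estimate the directed cross-lagged network for the first follow-up interval.

Each symptom at T1 is regressed on all nine symptoms at T0 plus covariates
(penalty-free) with a lasso penalty chosen by ten-fold cross-validation and
the one-standard-error rule.  Off-diagonal coefficients are cross-lagged
predictive paths; the diagonal holds autoregressive effects.
"""

import numpy as np

import panelnet as pn

truth = pn.default_ground_truth(seed=0)
panel = pn.simulate_panel(truth, n0=650, waves=2, seed=1)

net = pn.fit_clpn(panel, "T0", "T1", seed=3)
edges = net.edge_list()
cross = edges[~edges["autoregressive"]].sort_values("weight", key=abs,
                                                    ascending=False)
print("strongest cross-lagged paths (predictor at T0 → outcome at T1):")
print(cross.head(3).to_string(index=False))
# the generator's true paths are AcS→SOM (0.40), AcS→DEP (0.35), SuI→SuT (0.40);
# lasso shrinkage biases the recovered coefficients toward zero

dc = pn.directed_expected_influence(net)
print("\ndirected expected influence (z-scores):")
print(dc.table[["in_EI_z", "out_EI_z"]].round(2).to_string())
# high out-EI marks a symptom that drives others; high in-EI one that is driven
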