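"""Check robustness of the estimated networks to follow-up attrition.

Missing symptom cells are imputed m times by chained equations with
predictive mean matching, the analyses are repeated per completed dataset,
edge matrices are pooled by their entrywise mean, and agreement with the
complete-case analysis is summarized by Spearman rank correlations.
"""

import panelnet as pn
from panelnet.ggm import fit_wave_ggm
from panelnet.imputation import compare_spearman, impute_chained, pooled_networks

truth = pn.default_ground_truth(seed=0)
panel = pn.simulate_panel(truth, n0=650, waves=3, seed=1)  # ~30% lost by T1

imp = impute_chained(panel, m=10, seed=2, n_iter=5)
print("imputation:", imp.method_tag, f"(m = {imp.m})")

pooled_ggms, pooled_clpns = pooled_networks(imp, seed=3)
original = {w: fit_wave_ggm(panel, w) for w in panel.waves}
orig_clpns = {("T0", "T1"): pn.fit_clpn(panel, "T0", "T1", seed=3),
              ("T1", "T2"): pn.fit_clpn(panel, "T1", "T2", seed=3)}

report = compare_spearman(original, pooled_ggms, orig_clpns, pooled_clpns)
print("\nSpearman agreement, original vs pooled-imputation analysis:")
for w, rho in report.edges.items():
    print(f"  edges {w}: {rho:.3f}" if rho is not None else f"  edges {w}: n/a")
for pair, rho in report.paths.items():
    print(f"  cross-lagged paths {pair}: {rho:.3f}")
# values near 1 mean the network conclusions survive the missing data
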