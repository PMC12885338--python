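"""End-to-end analysis pipeline and its configuration.

Given any conforming panel CSV (simulated or real), reproduces the full
longitudinal network analysis: per-wave EBIC-glasso GGMs with centralities,
pairwise permutation invariance tests with Bonferroni adjustment, CLPNs for
consecutive wave pairs with in/out expected influence, bootstrap edge CIs,
difference tests and case-dropping CS reports for every network, and — when
missingness is present — the multiple-imputation sensitivity analysis.
Every artifact is linked to the config hash and master seed in a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bootstrap as bt
from .centrality import compute_centrality
from .clpn import directed_expected_influence, fit_clpn
from .ggm import center_within_wave, ebic_select
from .imputation import compare_spearman, impute_chained, pooled_networks
from .labels import COVARIATES, NODES
from .nct import bonferroni, nct
from .panel import PanelDataset, read_panel_csv

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_full_pipeline"]


@dataclass
class AnalysisConfig:
    """All tuning constants and seeds of one pipeline run (serialized into
    every output for provenance)."""

    input_path: str | None = None
    output_dir: str = "panelnet_out"
    node_labels: list[str] = field(default_factory=lambda: list(NODES))
    covariate_labels: list[str] = field(default_factory=lambda: list(COVARIATES))
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    clpn_n_lambda: int = 100
    clpn_lambda_min_ratio: float = 0.001
    bootstrap_B: int = 1000
    nct_permutations: int = 1000
    cs_drop_grid: list[float] = field(default_factory=lambda: list(bt.DEFAULT_DROP_GRID))
    cs_subsamples: int = 100
    mi_m: int = 20
    mi_iter: int = 10
    seed: int = 0
    run_bootstrap: bool = True
    run_cs: bool = True
    run_mi: bool = True
    display_threshold: float = 0.1

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        obj = yaml.safe_load(text)
        return cls(**obj)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _dump(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_full_pipeline(config: AnalysisConfig, panel: PanelDataset | None = None) -> dict:
    """Execute every analysis stage, writing artifacts under ``config.output_dir``.

    A stage failure is isolated: it is recorded in the manifest, downstream
    artifacts that depend on it are absent, and the manifest's ``ok`` flag is
    False (the CLI exits nonzero on that).  Reruns with an identical config
    and input produce byte-identical numeric outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if panel is None:
        if config.input_path is None:
            raise ValueError("config.input_path or an in-memory panel is required")
        panel = read_panel_csv(config.input_path, config.node_labels, config.covariate_labels)

    stamp = {"config": asdict(config), "config_hash": config.hash(), "seed": config.seed}
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed,
                      "stages": {}, "artifacts": [], "ok": True}
    seeds = np.random.SeedSequence(config.seed).generate_state(64) % np.uint32(2**31)
    waves = panel.waves
    pairs = list(zip(waves[:-1], waves[1:]))
    ebic_kw = dict(n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio)
    cv_kw = dict(n_lambda=config.clpn_n_lambda, lambda_min_ratio=config.clpn_lambda_min_ratio)

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
            manifest["stages"][name] = {"status": "ok",
                                        "seconds": round(time.perf_counter() - t0, 3)}
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        except Exception as err:  # noqa: BLE001 — isolate stage failures
            manifest["stages"][name] = {"status": "failed", "error": str(err),
                                        "seconds": round(time.perf_counter() - t0, 3)}
            manifest["ok"] = False
            logger.error("stage %s FAILED: %s", name, err)

    ggms: dict = {}
    scores: dict = {}

    def _ggm_stage():
        for w in waves:
            centred, moments = center_within_wave(panel, w)
            scores[w] = panel.complete_cases(w)
            fit = ebic_select(moments, gamma=config.gamma, **ebic_kw)
            ggms[w] = fit
            _dump({**{"labels": fit.labels, "W": fit.W.tolist(),
                      "lambda": fit.lambda_selected, "gamma": fit.gamma, "n": fit.n},
                   **stamp}, out / f"ggm_{w}.json")
            fit.edge_list().to_csv(out / f"edges_{w}.csv", index=False)
            fit.edge_list(display=True, display_threshold=config.display_threshold) \
               .to_csv(out / f"edges_{w}_display.csv", index=False)
            compute_centrality(fit.W, fit.labels).to_long(wave=w) \
                .to_csv(out / f"centrality_{w}.csv", index=False)
            manifest["artifacts"] += [f"ggm_{w}.json", f"edges_{w}.csv", f"centrality_{w}.csv"]

    stage("ggm", _ggm_stage)

    def _nct_stage():
        results = {}
        raw_ps = []
        for i, (wa, wb) in enumerate([(a, b) for k, a in enumerate(waves)
                                      for b in waves[k + 1:]]):
            ca = scores[wa] - scores[wa].mean()
            cb = scores[wb] - scores[wb].mean()
            res = nct(ca.to_numpy(), cb.to_numpy(),
                      n_permutations=config.nct_permutations, gamma=config.gamma,
                      seed=int(seeds[1 + i]), **ebic_kw)
            results[f"{wa}_vs_{wb}"] = res.to_json()
            raw_ps.append((f"{wa}_vs_{wb}", res.p_structure, res.p_global))
        m = len(raw_ps)
        for (key, ps, pg), ps_adj, pg_adj in zip(
                raw_ps, bonferroni([x[1] for x in raw_ps], m),
                bonferroni([x[2] for x in raw_ps], m)):
            results[key]["p_structure_bonferroni"] = ps_adj
            results[key]["p_global_bonferroni"] = pg_adj
            results[key]["bonferroni_m"] = m
        _dump({**results, **stamp}, out / "nct.json")
        manifest["artifacts"].append("nct.json")

    if "ggm" in manifest["stages"] and manifest["stages"]["ggm"]["status"] == "ok" \
            and len(waves) >= 2:
        stage("nct", _nct_stage)

    clpns: dict = {}

    def _clpn_stage():
        for i, (wa, wb) in enumerate(pairs):
            net = fit_clpn(panel, wa, wb, seed=int(seeds[10 + i]), **cv_kw)
            clpns[(wa, wb)] = net
            net.to_json(out / f"clpn_{wa}_{wb}.json", seed=int(seeds[10 + i]))
            net.edge_list().to_csv(out / f"clpn_edges_{wa}_{wb}.csv", index=False)
            dc = directed_expected_influence(net)
            dc.table.to_csv(out / f"clpn_centrality_{wa}_{wb}.csv")
            manifest["artifacts"] += [f"clpn_{wa}_{wb}.json", f"clpn_edges_{wa}_{wb}.csv",
                                      f"clpn_centrality_{wa}_{wb}.csv"]

    if len(waves) >= 2:
        stage("clpn", _clpn_stage)

    boots: dict = {}

    def _bootstrap_stage():
        report: dict = {}
        for i, w in enumerate(waves):
            est = bt.ggm_estimator(gamma=config.gamma, **ebic_kw)
            dist = bt.bootstrap_estimates(scores[w], est, B=config.bootstrap_B,
                                          seed=int(seeds[20 + i]), estimator_tag="ggm")
            boots[w] = dist
            ci = bt.edge_ci(dist)
            report[w] = {"edge_ci": {e: [float(ci.loc[e, "lower"]), float(ci.loc[e, "upper"])]
                                     for e in ci.index},
                         "n_failed": dist.n_failed, "B": dist.B}
        for wa, wb in pairs:
            diff_e = bt.difference_tests(boots[wa], "edges", other=boots[wb])
            diff_c = bt.difference_tests(boots[wa], "centrality", other=boots[wb])
            report[f"{wa}_vs_{wb}"] = {
                "edges_differ": {k: bool(v) for k, v in diff_e.items()},
                "centrality_differ": {idx: {k: bool(v) for k, v in s.items()}
                                      for idx, s in diff_c.items()},
            }
        for i, (wa, wb) in enumerate(pairs):
            wide = _pair_wide(panel, wa, wb)
            est = bt.clpn_estimator(wa, wb, seed=int(seeds[10 + i]),
                                    node_labels=panel.node_labels,
                                    covariate_labels=panel.covariate_labels, **cv_kw)
            dist = bt.bootstrap_estimates(wide, est, B=config.bootstrap_B,
                                          seed=int(seeds[30 + i]), estimator_tag="clpn")
            ci = bt.edge_ci(dist)
            report[f"clpn_{wa}_{wb}"] = {
                "n_nonzero_edges": int(np.count_nonzero(clpns[(wa, wb)].A)),
                "n_ci_excludes_zero": int(ci["excludes_zero"].sum()),
                "n_failed": dist.n_failed, "B": dist.B,
            }
        _dump({**report, **stamp}, out / "bootstrap.json")
        manifest["artifacts"].append("bootstrap.json")

    if config.run_bootstrap and manifest["ok"]:
        stage("bootstrap", _bootstrap_stage)

    def _cs_stage():
        report = {}
        for i, w in enumerate(waves):
            est = bt.ggm_estimator(gamma=config.gamma, **ebic_kw)
            rep = bt.case_dropping_cs(scores[w], est, drop_grid=config.cs_drop_grid,
                                      n_subsamples=config.cs_subsamples,
                                      seed=int(seeds[40 + i]))
            report[w] = rep.to_json()
        for i, (wa, wb) in enumerate(pairs):
            wide = _pair_wide(panel, wa, wb)
            est = bt.clpn_estimator(wa, wb, seed=int(seeds[10 + i]),
                                    node_labels=panel.node_labels,
                                    covariate_labels=panel.covariate_labels, **cv_kw)
            rep = bt.case_dropping_cs(wide, est, drop_grid=config.cs_drop_grid,
                                      n_subsamples=config.cs_subsamples,
                                      seed=int(seeds[50 + i]))
            report[f"clpn_{wa}_{wb}"] = rep.to_json()
        _dump({**report, **stamp}, out / "stability.json")
        manifest["artifacts"].append("stability.json")

    if config.run_cs and manifest["ok"]:
        stage("cs", _cs_stage)

    def _mi_stage():
        has_missing = panel.data[panel.node_labels].isna().any().any()
        if not has_missing:
            _dump({"skipped": "no missing cells", **stamp}, out / "sensitivity.json")
            manifest["artifacts"].append("sensitivity.json")
            return
        imp = impute_chained(panel, m=config.mi_m, seed=int(seeds[60]),
                             n_iter=config.mi_iter)
        pg, pc = pooled_networks(imp, gamma=config.gamma, seed=int(seeds[61]),
                                 ebic_kwargs=ebic_kw, cv_kwargs=cv_kw)
        rep = compare_spearman(ggms, pg, clpns, pc)
        _dump({**rep.to_json(), "m": imp.m, "method": imp.method_tag, **stamp},
              out / "sensitivity.json")
        manifest["artifacts"].append("sensitivity.json")

    if config.run_mi and manifest["ok"]:
        stage("mi", _mi_stage)

    _dump(manifest, out / "manifest.json")
    return manifest


def _pair_wide(panel: PanelDataset, wa: str, wb: str):
    """Wide pair-complete table used as the CLPN resampling unit."""
    import pandas as pd

    a = panel.complete_cases(wa)
    b = panel.complete_cases(wb)
    covs = panel.covariates().dropna(how="any")
    ids = a.index.intersection(b.index).intersection(covs.index).sort_values()
    wide = pd.concat([
        a.loc[ids].rename(columns={c: f"{c}_{wa}" for c in a.columns}),
        b.loc[ids].rename(columns={c: f"{c}_{wb}" for c in b.columns}),
        covs.loc[ids],
    ], axis=1)
    return wide.reset_index(drop=True)
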