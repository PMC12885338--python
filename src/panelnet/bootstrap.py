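"""Bootstrap accuracy and stability diagnostics for estimated networks.

Two resampling schemes, applicable to both the cross-sectional GGM and the
cross-lagged panel network through a common estimator protocol:

* nonparametric bootstrap (n-out-of-n with replacement) for percentile edge
  confidence intervals and bootstrap difference tests;
* case-dropping subset bootstrap for the correlation-stability (CS)
  coefficient: the largest tested proportion of cases that can be dropped
  while the subsample-vs-full-sample centrality correlation stays ≥ 0.70
  with at least 95% probability.  CS > 0.50 is read as excellent stability,
  0.25–0.50 as moderate, < 0.25 as insufficient.

An *estimator* is any callable mapping a row-resampled DataFrame to a
:class:`NetworkEstimate` (a named edge vector plus a node × index centrality
table); :func:`ggm_estimator` and :func:`clpn_estimator` build the two used
in practice.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import INDEX_NAMES, compute_centrality
from .ggm import EstimationError, SampleMoments, ebic_select
from .labels import COVARIATES
from .panel import PanelDataset

__all__ = ["NetworkEstimate", "BootstrapDistribution", "CSReport",
           "bootstrap_estimates", "edge_ci", "difference_tests",
           "case_dropping_cs", "ggm_estimator", "clpn_estimator",
           "stability_bands"]

logger = logging.getLogger(__name__)

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))


@dataclass
class NetworkEstimate:
    """Estimator output: named edge vector and node × index centrality table."""

    edges: pd.Series
    centrality: pd.DataFrame


def ggm_estimator(gamma: float = 0.5, labels: list[str] | None = None, **ebic_kwargs):
    """Estimator over a wave's raw score matrix (rows = participants)."""

    def estimate(scores: pd.DataFrame) -> NetworkEstimate:
        X = scores.to_numpy(float)
        if np.any(X.std(axis=0) == 0.0):
            raise EstimationError("zero-variance column in resample")
        S = np.corrcoef(X, rowvar=False)
        labs = labels if labels is not None else list(scores.columns)
        fit = ebic_select(SampleMoments(S=S, n=X.shape[0], labels=labs),
                          gamma=gamma, **ebic_kwargs)
        p = len(labs)
        iu = np.triu_indices(p, 1)
        edges = pd.Series(fit.W[iu],
                          index=[f"{labs[i]}--{labs[j]}" for i, j in zip(*iu)])
        cent = compute_centrality(fit.W, labs).table[INDEX_NAMES]
        return NetworkEstimate(edges=edges, centrality=cent)

    return estimate


def clpn_estimator(from_wave: str, to_wave: str, seed: int = 0,
                   node_labels: list[str] | None = None,
                   covariate_labels: list[str] | None = None, **cv_kwargs):
    """Estimator over a wide pair-complete table (columns ``DEP_T0`` … + covariates).

    The resampled wide rows are given fresh participant ids (bootstrap
    duplicates are distinct participants) and re-analysed end to end.
    """
    from .clpn import directed_expected_influence, fit_clpn

    def estimate(wide: pd.DataFrame) -> NetworkEstimate:
        nodes = node_labels if node_labels is not None else [
            c.rsplit("_", 1)[0] for c in wide.columns if c.endswith(f"_{from_wave}")]
        covs = covariate_labels if covariate_labels is not None else list(COVARIATES)
        rows = []
        for wave in (from_wave, to_wave):
            frame = wide[[f"{n}_{wave}" for n in nodes]].copy()
            frame.columns = nodes
            frame.insert(0, "wave", wave)
            frame.insert(0, "participant_id", [f"R{i:06d}" for i in range(len(wide))])
            for c in covs:
                frame[c] = wide[c].to_numpy()
            rows.append(frame)
        panel = PanelDataset(pd.concat(rows, ignore_index=True),
                             node_labels=list(nodes), covariate_labels=list(covs))
        net = fit_clpn(panel, from_wave, to_wave, seed=seed, **cv_kwargs)
        p = len(nodes)
        edges = pd.Series(net.A.ravel(),
                          index=[f"{nodes[i]}->{nodes[j]}" for i in range(p) for j in range(p)])
        cent = directed_expected_influence(net).table[["in_EI", "out_EI"]]
        return NetworkEstimate(edges=edges, centrality=cent)

    return estimate


@dataclass
class BootstrapDistribution:
    estimator_tag: str
    B: int
    edges: pd.DataFrame                       # B × edge labels
    centrality: dict[str, pd.DataFrame]       # index name → B × node labels
    seed: int
    n_failed: int = 0
    full: NetworkEstimate | None = None


def bootstrap_estimates(data: pd.DataFrame, estimator, B: int, seed: int = 0,
                        estimator_tag: str = "ggm",
                        include_identity: bool = False) -> BootstrapDistribution:
    """B nonparametric resamples of participants, estimator re-run per resample.

    Failed replicates are dropped and counted; more than 5% failures logs a
    warning in the report.  With `include_identity` the first replicate is the
    identity resample (useful for exactness checks).
    """
    n = len(data)
    rng = np.random.default_rng(seed)
    full = estimator(data)
    edge_rows, cent_rows = [], []
    n_failed = 0
    for b in range(B):
        if include_identity and b == 0:
            idx = np.arange(n)
        else:
            idx = rng.integers(0, n, n)
        sub = data.iloc[idx].reset_index(drop=True)
        try:
            est = estimator(sub)
        except (EstimationError, np.linalg.LinAlgError) as err:
            n_failed += 1
            logger.debug("replicate %d failed: %s", b, err)
            continue
        edge_rows.append(est.edges)
        cent_rows.append(est.centrality)
    if n_failed > 0.05 * B:
        logger.warning("%d of %d bootstrap replicates failed", n_failed, B)
    edges = pd.DataFrame(edge_rows).reset_index(drop=True)
    centrality = {
        name: pd.DataFrame([c[name] for c in cent_rows]).reset_index(drop=True)
        for name in (cent_rows[0].columns if cent_rows else [])
    }
    return BootstrapDistribution(estimator_tag=estimator_tag, B=B, edges=edges,
                                 centrality=centrality, seed=seed,
                                 n_failed=n_failed, full=full)


def edge_ci(dist: BootstrapDistribution, level: float = 0.95) -> pd.DataFrame:
    """Percentile interval at the (1−level)/2 and 1−(1−level)/2 quantiles."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    lo = (1.0 - level) / 2.0
    out = pd.DataFrame({
        "lower": dist.edges.quantile(lo),
        "upper": dist.edges.quantile(1.0 - lo),
    })
    out["excludes_zero"] = (out["lower"] > 0.0) | (out["upper"] < 0.0)
    return out


def difference_tests(dist: BootstrapDistribution, what: str = "edges",
                     level: float = 0.95,
                     other: BootstrapDistribution | None = None):
    """Bootstrap difference tests: a pair differs iff the percentile CI of the
    replicate-wise difference excludes zero.

    Within one distribution (`other` is None) every pair of edges — or, for
    centrality, every pair of nodes per index — is compared, returning
    symmetric boolean matrices.  With `other` given, matched elements of the
    two distributions are compared (element-wise across networks).
    """
    lo = (1.0 - level) / 2.0

    def _pairwise(frame: pd.DataFrame) -> pd.DataFrame:
        cols = frame.columns
        vals = frame.to_numpy()
        m = len(cols)
        sig = np.zeros((m, m), dtype=bool)
        for i in range(m):
            diff = vals[:, [i]] - vals
            ql = np.quantile(diff, lo, axis=0)
            qu = np.quantile(diff, 1.0 - lo, axis=0)
            sig[i] = (ql > 0.0) | (qu < 0.0)
        np.fill_diagonal(sig, False)
        return pd.DataFrame(sig | sig.T, index=cols, columns=cols)

    def _matched(a: pd.DataFrame, b: pd.DataFrame) -> pd.Series:
        common = a.columns.intersection(b.columns)
        nrep = min(len(a), len(b))
        diff = a[common].iloc[:nrep].to_numpy() - b[common].iloc[:nrep].to_numpy()
        ql = np.quantile(diff, lo, axis=0)
        qu = np.quantile(diff, 1.0 - lo, axis=0)
        return pd.Series((ql > 0.0) | (qu < 0.0), index=common)

    if what == "edges":
        return _matched(dist.edges, other.edges) if other is not None \
            else _pairwise(dist.edges)
    if what == "centrality":
        if other is not None:
            return {k: _matched(v, other.centrality[k]) for k, v in dist.centrality.items()
                    if k in other.centrality}
        return {k: _pairwise(v) for k, v in dist.centrality.items()}
    raise ValueError("what must be 'edges' or 'centrality'")


def _stability_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with degenerate conventions: a zero-variance vector
    (e.g. the all-zero strength profile of an empty network) correlates 0 with
    anything — the field's standard rule, which keeps an estimator that is
    'stable at being empty' from claiming maximal CS; identical non-constant
    vectors correlate exactly 1."""
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    if np.array_equal(a, b):
        return 1.0
    return float(np.corrcoef(a, b)[0, 1])


def stability_bands(cs: float) -> str:
    if cs > 0.50:
        return "excellent"
    if cs >= 0.25:
        return "moderate"
    return "insufficient"


@dataclass
class CSReport:
    """Correlation-stability coefficients with the subsample curves behind them."""

    drop_grid: tuple
    n_subsamples: int
    prob_ge_070: dict[str, np.ndarray]          # index tag → per-proportion probability
    cs_coefficient: dict[str, float]
    band: dict[str, str]
    correlations: dict[str, np.ndarray]         # index tag → levels × subsamples (NaN = failed)
    infeasible: list[float] = field(default_factory=list)
    seed: int = 0
    threshold: float = 0.70
    coverage: float = 0.95

    def to_json(self, path=None) -> dict:
        obj = {
            "drop_grid": list(self.drop_grid),
            "n_subsamples": self.n_subsamples,
            "prob_ge_070": {k: v.tolist() for k, v in self.prob_ge_070.items()},
            "cs_coefficient": self.cs_coefficient,
            "band": self.band,
            "infeasible": self.infeasible,
            "seed": self.seed,
            "interpretation": "excellent > 0.50; moderate 0.25-0.50; insufficient < 0.25",
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True)
        return obj


def case_dropping_cs(data: pd.DataFrame, estimator,
                     drop_grid=DEFAULT_DROP_GRID, n_subsamples: int = 100,
                     seed: int = 0, include_edges: bool = True) -> CSReport:
    """Case-dropping subset bootstrap and CS coefficient per centrality index.

    For each drop proportion p, `n_subsamples` subsamples of round((1−p)·n)
    cases are drawn without replacement and the estimator re-run; each index
    vector (and, with `include_edges`, the edge-weight vector under the tag
    ``"edge"``) is Pearson-correlated with its full-sample counterpart.  The
    CS coefficient is the largest tested proportion whose correlation is
    ≥ 0.70 in at least 95% of subsamples.
    """
    drop_grid = tuple(sorted(float(p) for p in drop_grid))
    if any(not 0.0 < p < 1.0 for p in drop_grid):
        raise ValueError("drop proportions must lie in (0, 1)")
    n = len(data)
    rng = np.random.default_rng(seed)
    full = estimator(data)
    tags = list(full.centrality.columns) + (["edge"] if include_edges else [])
    full_vec = {t: (full.edges.to_numpy() if t == "edge"
                    else full.centrality[t].to_numpy()) for t in tags}

    corr = {t: np.full((len(drop_grid), n_subsamples), np.nan) for t in tags}
    infeasible: list[float] = []
    for li, p_drop in enumerate(drop_grid):
        m = int(round((1.0 - p_drop) * n))
        n_ok = 0
        for si in range(n_subsamples):
            idx = rng.choice(n, size=m, replace=False)
            try:
                est = estimator(data.iloc[np.sort(idx)].reset_index(drop=True))
            except (EstimationError, np.linalg.LinAlgError, ValueError):
                continue
            n_ok += 1
            for t in tags:
                vec = est.edges.to_numpy() if t == "edge" else est.centrality[t].to_numpy()
                corr[t][li, si] = _stability_correlation(full_vec[t], vec)
        if n_ok == 0:
            infeasible.append(p_drop)

    prob = {}
    cs = {}
    band = {}
    for t in tags:
        vals = []
        for li in range(len(drop_grid)):
            row = corr[t][li]
            ok = ~np.isnan(row)  # failed subsamples are dropped, not counted against
            vals.append(np.mean(row[ok] >= 0.70) if ok.any() else np.nan)
        prob[t] = np.array(vals)
        feasible = [drop_grid[li] for li in range(len(drop_grid))
                    if drop_grid[li] not in infeasible and prob[t][li] >= 0.95]
        cs[t] = max(feasible) if feasible else 0.0
        band[t] = stability_bands(cs[t])
    return CSReport(drop_grid=drop_grid, n_subsamples=n_subsamples,
                    prob_ge_070=prob, cs_coefficient=cs, band=band,
                    correlations=corr, infeasible=infeasible, seed=seed)
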