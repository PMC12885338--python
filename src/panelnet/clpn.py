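"""Cross-lagged panel network estimation by node-wise cross-validated lasso.

For each symptom Y at the later wave, Y(t) is regressed on all nine symptoms
at t−1 plus four covariates (age, gender, education, disease duration).  The
lasso penalty is selected per outcome by ten-fold cross-validation with the
Gaussian deviance (held-out residual sum of squares), taking the largest λ
within one standard error of the minimum (the λ.1se rule).  Covariates are
penalty-free: they are always adjusted for, never shrunk.  Assembling the
nine coefficient vectors gives the directed 9×9 adjacency matrix — the
autoregressive effects on the diagonal, cross-lagged effects off it.

Penalty-free covariates are handled by exact partialling-out: with only the
symptom block penalized, the joint solution equals the lasso of covariate-
residualized y on covariate-residualized (standardized) predictors, after
which the covariate coefficients are recovered by least squares.  The symptom
predictors are standardized internally for the penalty and the coefficients
are returned on the original centred-score scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .centrality import _zscore
from .ggm import EstimationError, center_within_wave
from .labels import COVARIATES
from .panel import PanelDataset

__all__ = ["LaggedDesign", "LassoPath", "DirectedNetwork", "DirectedCentrality",
           "build_lagged_design", "cv_lasso", "fit_clpn", "directed_expected_influence"]

logger = logging.getLogger(__name__)


@dataclass
class LaggedDesign:
    """Complete-case design for one outcome regression of a wave pair."""

    X: pd.DataFrame          # lagged symptom predictors + covariates, no missing cells
    y: pd.Series             # centred outcome at the later wave
    outcome_label: str
    n_complete: int
    penalized: list[str]     # predictor columns that carry the lasso penalty


@dataclass
class LassoPath:
    """Cross-validated deviance path over a decreasing λ grid."""

    lambda_grid: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float


@dataclass
class CVLassoFit:
    path: LassoPath
    coef: pd.Series            # penalized coefficients, original centred-score scale
    covariate_coef: pd.Series  # penalty-free coefficients, original covariate scale
    intercept: float
    coef_at_lambda_min: pd.Series
    seed: object = None


@dataclass
class DirectedNetwork:
    """9×9 lagged coefficient matrix: A[i, j] = effect of symptom i at t−1 on j at t."""

    A: np.ndarray
    covariate_coefs: np.ndarray   # 4×9
    wave_pair: tuple[str, str]
    n_per_outcome: dict[str, int]
    labels: list[str] = field(default_factory=list)
    covariate_labels: list[str] = field(default_factory=lambda: list(COVARIATES))

    def edge_list(self, display: bool = False, display_threshold: float = 0.1) -> pd.DataFrame:
        rows = []
        p = self.A.shape[0]
        for i in range(p):
            for j in range(p):
                w = self.A[i, j]
                if w == 0.0:
                    continue
                if display and abs(w) <= display_threshold:
                    continue
                rows.append({"from": self.labels[i], "to": self.labels[j],
                             "weight": w, "autoregressive": i == j})
        return pd.DataFrame(rows, columns=["from", "to", "weight", "autoregressive"])

    def to_json(self, path=None, seed=None) -> dict:
        obj = {
            "labels": self.labels,
            "A": self.A.tolist(),
            "covariate_labels": self.covariate_labels,
            "covariate_coefs": self.covariate_coefs.tolist(),
            "wave_pair": list(self.wave_pair),
            "n_per_outcome": self.n_per_outcome,
            "seed": seed,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True)
        return obj


@dataclass
class DirectedCentrality:
    """In/out expected influence (diagonal excluded), raw and z-scored."""

    table: pd.DataFrame
    k: int


def _pair_complete(panel: PanelDataset, from_wave: str, to_wave: str):
    """Centred lagged predictors + covariates and centred outcomes, pair-complete."""
    centred_from, _ = center_within_wave(panel, from_wave)
    centred_to, _ = center_within_wave(panel, to_wave)
    covs = panel.covariates().dropna(how="any")
    ids = centred_from.index.intersection(centred_to.index).intersection(covs.index)
    ids = ids.sort_values()  # stable participant ordering for reproducible folds
    X = pd.concat([centred_from.loc[ids], covs.loc[ids]], axis=1)
    Y = centred_to.loc[ids]
    return X, Y


def build_lagged_design(panel: PanelDataset, from_wave: str, to_wave: str,
                        outcome: str) -> LaggedDesign:
    """Design for one outcome: listwise-complete across both waves and covariates."""
    X, Y = _pair_complete(panel, from_wave, to_wave)
    if outcome not in Y.columns:
        raise ValueError(f"unknown outcome {outcome!r}")
    n = len(X)
    if n < X.shape[1] + 1:
        raise EstimationError(
            f"only {n} complete cases across {from_wave}->{to_wave}; "
            f"need at least {X.shape[1] + 1}"
        )
    penalized = [c for c in X.columns if c not in panel.covariate_labels]
    return LaggedDesign(X=X, y=Y[outcome], outcome_label=outcome,
                        n_complete=n, penalized=penalized)


def _ols_coefs(Z: np.ndarray, targets: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(Z, targets, rcond=None)[0]


def cv_lasso(design: LaggedDesign, n_folds: int = 10,
             penalty_free: list[str] | None = None, seed=0,
             n_lambda: int = 100, lambda_min_ratio: float = 0.001) -> CVLassoFit:
    """Lasso with k-fold CV deviance and λ.1se selection.

    Deviance is the held-out mean squared error (Gaussian deviance up to a
    constant); cv_se is the standard deviation of per-fold deviances divided
    by √n_folds.  Columns named in `penalty_free` carry zero penalty.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    n = design.n_complete
    if n < n_folds:
        raise EstimationError(f"{n} rows cannot be split into {n_folds} folds")
    free = [c for c in (penalty_free if penalty_free is not None else COVARIATES)
            if c in design.X.columns]
    pen = [c for c in design.X.columns if c not in free]

    Xp = design.X[pen].to_numpy(float)
    y = design.y.to_numpy(float)
    mu, sd = Xp.mean(axis=0), Xp.std(axis=0)
    dead = [pen[k] for k in np.flatnonzero(sd == 0.0)]
    if dead:
        raise EstimationError(f"zero-variance penalized predictor(s): {dead}")
    Xs = (Xp - mu) / sd
    Z = np.column_stack([np.ones(n), design.X[free].to_numpy(float)]) if free \
        else np.ones((n, 1))

    ay = _ols_coefs(Z, y)
    AX = _ols_coefs(Z, Xs)
    yr = y - Z @ ay
    Xr = Xs - Z @ AX
    lam_max = float(np.max(np.abs(Xr.T @ yr)) / n)
    if lam_max <= 0.0:
        lam_max = 1e-3
    grid = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs_full, _ = lasso_path(Xr, yr, alphas=grid)

    fold_dev = np.empty((n_folds, n_lambda))
    attempt_seed = seed
    for attempt in range(10):
        rng = np.random.default_rng(attempt_seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        if all(np.std(y[np.setdiff1d(perm, f)]) > 0 for f in folds):
            break
        logger.warning("fold with zero outcome variance; reshuffling folds")
        attempt_seed = [attempt_seed, attempt] if np.isscalar(attempt_seed) \
            else list(attempt_seed) + [attempt]
    for fi, test_idx in enumerate(folds):
        train = np.setdiff1d(perm, test_idx)
        ayf = _ols_coefs(Z[train], y[train])
        AXf = _ols_coefs(Z[train], Xs[train])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs_f, _ = lasso_path(Xs[train] - Z[train] @ AXf,
                                       y[train] - Z[train] @ ayf, alphas=grid)
        # ŷ_test(λ) = Xs·β + Z·(a_y − A_X·β), all from the training fold
        alpha_f = ayf[:, None] - AXf @ coefs_f
        pred = Xs[test_idx] @ coefs_f + Z[test_idx] @ alpha_f
        fold_dev[fi] = np.mean((y[test_idx, None] - pred) ** 2, axis=0)

    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))
    thr = cv_mean[i_min] + cv_se[i_min]
    i_1se = int(np.flatnonzero(cv_mean <= thr)[0])  # grid is decreasing: first = largest λ
    path = LassoPath(lambda_grid=grid, cv_mean=cv_mean, cv_se=cv_se,
                     lambda_min=float(grid[i_min]), lambda_1se=float(grid[i_1se]))

    def _coefs_at(idx: int) -> pd.Series:
        return pd.Series(coefs_full[:, idx] / sd, index=pen)

    beta_std = coefs_full[:, i_1se]
    alpha = ay - AX @ beta_std
    cov_coef = pd.Series(alpha[1:], index=free) if free else pd.Series(dtype=float)
    return CVLassoFit(path=path, coef=_coefs_at(i_1se), covariate_coef=cov_coef,
                      intercept=float(alpha[0]), coef_at_lambda_min=_coefs_at(i_min),
                      seed=seed)


def fit_clpn(panel: PanelDataset, from_wave: str, to_wave: str, seed: int = 0,
             **cv_kwargs) -> DirectedNetwork:
    """Nine node-wise CV-lasso regressions assembled into a directed network.

    Per-outcome fold seeds are derived from the master seed and the outcome
    index, and folds are keyed to the sorted participant ordering, so the
    result is invariant to input row order.
    """
    nodes = panel.node_labels
    A = np.zeros((len(nodes), len(nodes)))
    cov_coefs = np.zeros((len(panel.covariate_labels), len(nodes)))
    n_per_outcome: dict[str, int] = {}
    X, Y = _pair_complete(panel, from_wave, to_wave)  # shared across the 9 outcomes
    n = len(X)
    if n < X.shape[1] + 1:
        raise EstimationError(
            f"only {n} complete cases across {from_wave}->{to_wave}; "
            f"need at least {X.shape[1] + 1}"
        )
    penalized = [c for c in X.columns if c not in panel.covariate_labels]
    for k, outcome in enumerate(nodes):
        design = LaggedDesign(X=X, y=Y[outcome], outcome_label=outcome,
                              n_complete=n, penalized=penalized)
        try:
            fit = cv_lasso(design, penalty_free=panel.covariate_labels,
                           seed=[seed, k], **cv_kwargs)
        except EstimationError as err:
            raise EstimationError(f"outcome {outcome!r}: {err}") from err
        for i, pred in enumerate(nodes):
            A[i, k] = fit.coef.get(pred, 0.0)
        for c, cov in enumerate(panel.covariate_labels):
            cov_coefs[c, k] = fit.covariate_coef.get(cov, 0.0)
        n_per_outcome[outcome] = design.n_complete
    return DirectedNetwork(A=A, covariate_coefs=cov_coefs,
                           wave_pair=(from_wave, to_wave),
                           n_per_outcome=n_per_outcome, labels=list(nodes),
                           covariate_labels=list(panel.covariate_labels))


def directed_expected_influence(net: DirectedNetwork) -> DirectedCentrality:
    """in-EI_i = Σ_{j≠i} A[j, i]; out-EI_i = Σ_{j≠i} A[i, j]; z-scored over nodes."""
    A = np.asarray(net.A, float)
    if not np.all(np.isfinite(A)):
        raise ValueError("directed network contains non-finite entries")
    off = A - np.diag(np.diag(A))
    in_ei = off.sum(axis=0)
    out_ei = off.sum(axis=1)
    frame = pd.DataFrame({
        "in_EI": in_ei, "out_EI": out_ei,
        "in_EI_z": _zscore(in_ei), "out_EI_z": _zscore(out_ei),
    }, index=net.labels)
    return DirectedCentrality(table=frame, k=A.shape[0] - 1)
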