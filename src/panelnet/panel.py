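"""Panel data container and CSV readers/writers.

A :class:`PanelDataset` holds one record per (participant, wave): nine
symptom-domain totals plus four baseline covariates.  Symptom cells may be
missing (NaN); the reader accepts arbitrary missingness patterns — monotone
dropout is a property of the simulator, never enforced on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import COVARIATES, NODES, WAVES


class PanelError(ValueError):
    """Raised for malformed panel inputs."""


@dataclass
class PanelDataset:
    """Participant × wave table of symptom totals and covariates.

    Parameters
    ----------
    data
        Long-format frame with columns ``participant_id``, ``wave``, the nine
        symptom labels and the four covariate labels.  One row per
        (participant, wave); symptom cells may be NaN.
    """

    data: pd.DataFrame
    node_labels: list[str] = field(default_factory=lambda: list(NODES))
    covariate_labels: list[str] = field(default_factory=lambda: list(COVARIATES))

    def __post_init__(self) -> None:
        required = ["participant_id", "wave", *self.node_labels, *self.covariate_labels]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise PanelError(f"panel is missing required columns: {missing}")
        dup = self.data.duplicated(subset=["participant_id", "wave"])
        if dup.any():
            offenders = self.data.loc[dup, ["participant_id", "wave"]].to_records(index=False)
            raise PanelError(f"duplicate (participant, wave) records: {list(offenders)[:10]}")
        self.data = self.data.sort_values(["participant_id", "wave"], kind="mergesort").reset_index(drop=True)

    @property
    def waves(self) -> list[str]:
        order = {w: i for i, w in enumerate(WAVES)}
        present = self.data["wave"].unique().tolist()
        return sorted(present, key=lambda w: order.get(w, 99))

    def wave_scores(self, wave: str) -> pd.DataFrame:
        """Symptom scores at one wave, indexed by participant (NaN rows kept)."""
        sub = self.data[self.data["wave"] == wave]
        if sub.empty:
            raise PanelError(f"wave {wave!r} not present in panel")
        return sub.set_index("participant_id")[self.node_labels]

    def complete_cases(self, wave: str) -> pd.DataFrame:
        """Rows at `wave` with all nine symptoms observed."""
        scores = self.wave_scores(wave)
        return scores.dropna(axis=0, how="any")

    def covariates(self) -> pd.DataFrame:
        """Baseline covariates, one row per participant (first record wins)."""
        first = self.data.drop_duplicates(subset="participant_id", keep="first")
        return first.set_index("participant_id")[self.covariate_labels]

    def wide(self) -> pd.DataFrame:
        """One row per participant; symptom columns suffixed by wave (DEP_T0, ...)."""
        parts = []
        for w in self.waves:
            scores = self.wave_scores(w)
            scores = scores.rename(columns={c: f"{c}_{w}" for c in scores.columns})
            parts.append(scores)
        wide = pd.concat(parts, axis=1)
        return wide.join(self.covariates())

    def n_per_wave(self) -> dict[str, int]:
        return {w: len(self.complete_cases(w)) for w in self.waves}

    def missingness_summary(self) -> pd.DataFrame:
        rows = []
        for w in self.waves:
            scores = self.wave_scores(w)
            rows.append({
                "wave": w,
                "n_records": len(scores),
                "n_complete": len(scores.dropna(how="any")),
                "pct_missing_cells": float(scores.isna().to_numpy().mean() * 100.0),
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        cols = ["participant_id", "wave", *self.node_labels, *self.covariate_labels]
        self.data[cols].to_csv(path, index=False)

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.data.copy(), list(self.node_labels), list(self.covariate_labels))


def read_panel_csv(path, node_labels: list[str] | None = None,
                   covariate_labels: list[str] | None = None) -> PanelDataset:
    """Read a wide panel CSV (one row per participant-wave; empty cells missing).

    Raises :class:`PanelError` naming the missing column, the duplicate
    (participant, wave) pairs, or the row/column coordinates of an
    unparseable numeric cell.
    """
    nodes = list(node_labels) if node_labels else list(NODES)
    covs = list(covariate_labels) if covariate_labels else list(COVARIATES)
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    required = ["participant_id", "wave", *nodes, *covs]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise PanelError(f"{path}: missing required column(s) {missing}")
    numeric_cols = nodes + covs
    out = raw.copy()
    for col in numeric_cols:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelError(
                f"{path}: unparseable numeric value {raw[col].iloc[row]!r} "
                f"at row {row + 2} (1-based, incl. header), column {col!r}"
            )
        out[col] = converted
    return PanelDataset(out[required], nodes, covs)
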