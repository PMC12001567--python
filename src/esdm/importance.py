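"""Permutation variable importance and per-variable response curves.

Importance of a variable is the mean, over permutations, of one minus the
Pearson correlation between the model's predictions on intact data and its
predictions after permuting that variable's column, clipped at zero and
expressed as a percent.  A variable the model never uses therefore scores 0,
and the percentages are deliberately unnormalized (they need not sum to 100).
An AUC-drop variant is available for sensitivity analysis.

Response curves sweep one variable across its observed range while holding
every other variable at its data mean, tracing the model's partial response —
the standard way to visually recover a species' fitted niche along each
environmental gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import auc
from .exceptions import EmptyDataError


@dataclass
class ImportanceReport:
    table: pd.DataFrame  # columns: variable, importance_pct, sd_pct
    method: str

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values(
            "importance_pct", ascending=False, kind="stable"
        ).reset_index(drop=True)


def variable_importance(
    model,
    rows: pd.DataFrame,
    n_permutations: int = 10,
    seed: int | np.random.Generator = 0,
    method: str = "correlation",
    labels=None,
) -> ImportanceReport:
    """Permutation importance of every column of ``rows`` for ``model``.

    ``method="correlation"`` (default) needs no labels; ``method="auc"``
    measures the drop in AUC and requires binary ``labels``.
    """
    if len(rows) < 20:
        raise EmptyDataError("need at least 20 evaluation rows")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if method not in ("correlation", "auc"):
        raise ValueError(f"unknown importance method {method!r}")
    if method == "auc" and labels is None:
        raise ValueError("AUC-drop importance requires labels")
    rng = np.random.default_rng(seed)
    base = np.asarray(model.predict(rows), float)
    if np.ptp(base) == 0:
        raise EmptyDataError("model predictions are constant: correlation undefined")
    base_auc = auc(base, labels) if method == "auc" else None
    records = []
    for var in rows.columns:
        scores = np.empty(n_permutations)
        for k in range(n_permutations):
            shuffled = rows.copy()
            shuffled[var] = rng.permutation(shuffled[var].to_numpy())
            perm_pred = np.asarray(model.predict(shuffled), float)
            if method == "correlation":
                if np.ptp(perm_pred) == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(base, perm_pred)[0, 1])
                scores[k] = max(1.0 - r, 0.0)
            else:
                scores[k] = max(base_auc - auc(perm_pred, labels), 0.0)
        records.append(
            {
                "variable": var,
                "importance_pct": 100.0 * scores.mean(),
                "sd_pct": 100.0 * (scores.std(ddof=1) if n_permutations > 1 else 0.0),
            }
        )
    return ImportanceReport(table=pd.DataFrame(records), method=method)


def response_curve(
    model,
    rows: pd.DataFrame,
    variable: str,
    n_grid: int = 100,
    conditioning: str = "mean",
) -> pd.DataFrame:
    """Partial response of ``model`` to ``variable``: a strictly increasing
    grid over the observed range, other variables held at their data mean (or
    median).  Returns columns ``value`` and ``prediction`` (in [0,1])."""
    if variable not in rows.columns:
        raise KeyError(f"variable {variable!r} not among the model's data columns")
    if n_grid < 10:
        raise ValueError("n_grid must be >= 10")
    if conditioning not in ("mean", "median"):
        raise ValueError(f"unknown conditioning rule {conditioning!r}")
    v = rows[variable].to_numpy(float)
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise ValueError(f"variable {variable!r} has zero-width range in the data")
    grid = np.linspace(lo, hi, n_grid)
    agg = rows.mean() if conditioning == "mean" else rows.median()
    profile = pd.DataFrame({c: np.full(n_grid, agg[c]) for c in rows.columns})
    profile[variable] = grid
    pred = np.clip(np.asarray(model.predict(profile), float), 0.0, 1.0)
    return pd.DataFrame({"value": grid, "prediction": pred})
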