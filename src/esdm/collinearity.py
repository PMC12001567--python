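"""Variance-inflation-factor screening of candidate predictors.

Two elimination procedures mirror the usdm-style workflow: a pairwise
correlation-guided pass (drop the higher-VIF member of the most correlated
pair until no |r| exceeds the threshold) and a stepwise max-VIF pass (drop the
worst VIF until all fall below the threshold).  Defaults are |r| ≤ 0.75 and
VIF ≤ 5, the conventional conservative cutoffs.  Ties — equal |r| pairs or
equal max VIF — are broken by column order of the input table, which makes
both procedures deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CollinearityError

DEFAULT_VIF_THRESHOLD = 5.0
DEFAULT_CORR_THRESHOLD = 0.75

#: R² this close to 1 is treated as exact linear dependence → infinite VIF
_SINGULAR_R2 = 1.0 - 1e-10


@dataclass
class VifReport:
    """Outcome of an elimination run: retained variables (with final VIF) and
    removals in order, each tagged with the rule that fired and the value at
    removal (the |r| of the offending pair, or the VIF)."""

    retained: dict[str, float]
    removed: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def retained_names(self) -> list[str]:
        return list(self.retained)

    @property
    def removed_names(self) -> list[str]:
        return [name for name, _, _ in self.removed]

    def to_dict(self) -> dict:
        return {
            "retained": {k: float(v) for k, v in self.retained.items()},
            "removed": [
                {"variable": n, "reason": r, "value": float(v)} for n, r, v in self.removed
            ],
        }


def _clean(features: pd.DataFrame) -> pd.DataFrame:
    X = features.apply(pd.to_numeric).dropna(axis=0)
    n, p = X.shape
    if p < 2:
        raise CollinearityError(f"need at least 2 variables, got {p}")
    if n <= p:
        raise CollinearityError(f"need n > p rows after dropping missing values (n={n}, p={p})")
    const = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if const:
        raise CollinearityError(f"constant column(s): {const}")
    return X


def vif(features: pd.DataFrame) -> pd.Series:
    """Per-variable VIF_j = 1/(1−R²_j), R²_j from regressing column j on the rest.

    Exact linear dependence is reported as ``inf``.  Rows with missing values
    are dropped first; constant columns raise :class:`CollinearityError`.
    """
    X = _clean(features)
    values = X.to_numpy(float)
    values = values - values.mean(axis=0)
    n, p = values.shape
    out = {}
    for j, name in enumerate(X.columns):
        yj = values[:, j]
        others = np.delete(values, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = float(yj @ yj)
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out[name] = np.inf if r2 >= _SINGULAR_R2 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def _vif_or_one(X: pd.DataFrame) -> pd.Series:
    """VIF of the current set; a single surviving column has VIF 1 by definition."""
    if X.shape[1] == 1:
        return pd.Series({X.columns[0]: 1.0}, name="VIF")
    return vif(X)


def _max_abs_corr_pair(X: pd.DataFrame) -> tuple[str, str, float]:
    corr = X.corr().abs().to_numpy()
    cols = list(X.columns)
    best = (cols[0], cols[1], -1.0)
    p = len(cols)
    for i in range(p):
        for j in range(i + 1, p):
            if corr[i, j] > best[2]:  # strict > keeps the first pair on ties
                best = (cols[i], cols[j], float(corr[i, j]))
    return best


def _stepwise(X: pd.DataFrame, vif_threshold: float, removed: list) -> pd.DataFrame:
    while X.shape[1] >= 1:
        vifs = _vif_or_one(X)
        worst = vifs.idxmax()  # first occurrence wins on ties (column order)
        if vifs[worst] <= vif_threshold:
            break
        removed.append((worst, "vif", float(vifs[worst])))
        X = X.drop(columns=[worst])
    return X


def vifstep(features: pd.DataFrame, vif_threshold: float = DEFAULT_VIF_THRESHOLD) -> VifReport:
    """Repeatedly drop the max-VIF variable until all VIFs ≤ threshold."""
    X = _clean(features)
    removed: list[tuple[str, str, float]] = []
    X = _stepwise(X, vif_threshold, removed)
    return VifReport(retained=_vif_or_one(X).to_dict(), removed=removed)


def vifcor(
    features: pd.DataFrame,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    vif_threshold: float = DEFAULT_VIF_THRESHOLD,
) -> VifReport:
    """Correlation-guided elimination followed by a VIF safety pass.

    While the most correlated pair exceeds ``corr_threshold``, its higher-VIF
    member is dropped (value recorded = the pair's |r|).  The survivors are
    then run through the stepwise max-VIF rule so that every retained variable
    also satisfies VIF ≤ ``vif_threshold``.
    """
    X = _clean(features)
    removed: list[tuple[str, str, float]] = []
    while X.shape[1] >= 2:
        a, b, r = _max_abs_corr_pair(X)
        if r <= corr_threshold:
            break
        vifs = _vif_or_one(X)
        # drop the higher-VIF member; tie → the earlier column
        drop = a if vifs[a] >= vifs[b] else b
        removed.append((drop, "correlation", r))
        X = X.drop(columns=[drop])
    X = _stepwise(X, vif_threshold, removed)
    return VifReport(retained=_vif_or_one(X).to_dict(), removed=removed)
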