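"""TSS-weighted ensembles of member suitability models.

Member weights are proportional to each member's true skill statistic on its
test data, clipped below at zero — a below-chance member contributes nothing
rather than subtracting signal.  The ensemble prediction is the weighted mean
of member predictions, hence a convex combination bounded by the pointwise
member min and max.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import EsdmError, NoSkillError
from .raster_io import EnvStack
from .sdm_fit import AveragedModel, FittedModel

Member = FittedModel | AveragedModel


@dataclass
class EnsembleModel:
    members: list[Member]
    member_tss: list[float]
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("ensemble requires at least 2 members")
        if len(self.members) != len(self.member_tss):
            raise ValueError("one TSS per member required")
        clipped = np.clip(np.asarray(self.member_tss, float), 0.0, None)
        total = clipped.sum()
        if total <= 0:
            raise NoSkillError("all member TSS <= 0: no skillful member to weight")
        self.weights = clipped / total

    @property
    def variables(self) -> list[str]:
        out: list[str] = []
        for m in self.members:
            out.extend(v for v in m.variables if v not in out)
        return out

    def predict(self, X) -> np.ndarray:
        return ensemble_predict_rows(self, X)

    def predict_map(self, stack: EnvStack) -> np.ndarray:
        return ensemble_predict(self, stack)


def make_ensemble(members_with_tss: Sequence[tuple[Member, float]]) -> EnsembleModel:
    """Build an ensemble with weight_i = max(TSS_i, 0) / Σ max(TSS_j, 0)."""
    members = [m for m, _ in members_with_tss]
    tss = [t for _, t in members_with_tss]
    return EnsembleModel(members=members, member_tss=tss)


def ensemble_predict_rows(em: EnsembleModel, X) -> np.ndarray:
    """Weighted-mean prediction on feature rows; output in [0,1]."""
    preds = []
    for member, w in zip(em.members, em.weights):
        if w == 0.0:
            preds.append(np.zeros(len(X)))
            continue
        try:
            preds.append(np.asarray(member.predict(X), float))
        except Exception as exc:
            raise EsdmError(f"member {member.algorithm!r} failed to predict: {exc!r}") from exc
    return np.clip(np.einsum("m,mn->n", em.weights, np.vstack(preds)), 0.0, 1.0)


def ensemble_predict(em: EnsembleModel, stack: EnvStack) -> np.ndarray:
    """Per-cell weighted mean of member maps; NaN propagated at nodata."""
    out = np.zeros(stack.shape)
    for member, w in zip(em.members, em.weights):
        if w == 0.0:
            continue
        try:
            grid = member.predict_map(stack)
        except Exception as exc:
            raise EsdmError(f"member {member.algorithm!r} failed to predict: {exc!r}") from exc
        out = out + w * grid
    out = np.clip(out, 0.0, 1.0)
    out[stack.nodata_mask] = np.nan
    return out
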