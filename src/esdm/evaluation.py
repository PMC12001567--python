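"""Model assessment: confusion counts, threshold metrics, AUC and the MTSS rule.

Conventions fixed here so that confusion counts are bit-reproducible:

* a score exactly equal to the threshold predicts presence (``>=``);
* the confusion cells follow the standard presence/absence layout —
  ``a`` presences predicted present, ``b`` absences predicted present,
  ``c`` presences predicted absent, ``d`` absences predicted absent;
* TSS = sensitivity + specificity − 1, ranging −1 (inverted) to +1 (perfect),
  insensitive to prevalence;
* kappa is Cohen's chance-corrected agreement;
* AUC is the rank-based (Mann–Whitney) probability that a random presence
  outscores a random absence, ties counted half;
* the MTSS threshold is the candidate (unique observed scores plus 0 and 1)
  maximizing sensitivity + specificity, ties resolved to the lowest threshold —
  it balances commission (over-prediction) and omission (under-prediction)
  errors when converting continuous suitability to presence/absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import EmptyDataError


@dataclass(frozen=True)
class ConfusionCounts:
    a: int  # presences correctly predicted present
    b: int  # absences wrongly predicted present
    c: int  # presences wrongly predicted absent
    d: int  # absences correctly predicted absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EvalResult:
    threshold: float
    overall_accuracy: float
    sensitivity: float
    specificity: float
    tss: float
    kappa: float
    auc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "overall_accuracy": self.overall_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tss": self.tss,
            "kappa": self.kappa,
            "auc": self.auc,
        }


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.size == 0:
        raise EmptyDataError("no scores provided")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0 = absence, 1 = presence)")
    return scores, labels


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Tally a/b/c/d at the given threshold (score ≥ threshold ⇒ presence)."""
    scores, labels = _check_scores_labels(scores, labels)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0,1], got {threshold}")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        a=int((pred & pos).sum()),
        b=int((pred & ~pos).sum()),
        c=int((~pred & pos).sum()),
        d=int((~pred & ~pos).sum()),
    )


def metrics(cc: ConfusionCounts, threshold: float = float("nan")) -> EvalResult:
    """Overall accuracy (a+d)/n, sensitivity a/(a+c), specificity d/(b+d),
    TSS = sensitivity + specificity − 1, and Cohen's kappa."""
    if cc.a + cc.c == 0 or cc.b + cc.d == 0:
        raise EmptyDataError(
            "metrics undefined: need at least one observed presence and one observed absence"
        )
    n = cc.n
    sens = cc.a / (cc.a + cc.c)
    spec = cc.d / (cc.b + cc.d)
    oa = (cc.a + cc.d) / n
    tss = sens + spec - 1.0
    p_e = ((cc.a + cc.b) * (cc.a + cc.c) + (cc.c + cc.d) * (cc.b + cc.d)) / n**2
    kappa = 0.0 if p_e == 1.0 else (oa - p_e) / (1.0 - p_e)
    return EvalResult(
        threshold=threshold,
        overall_accuracy=oa,
        sensitivity=sens,
        specificity=spec,
        tss=tss,
        kappa=kappa,
    )


def auc(scores, labels) -> float:
    """Rank-based AUC: P(score_presence > score_absence), ties counted half."""
    scores, labels = _check_scores_labels(scores, labels)
    n1 = int((labels == 1).sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise EmptyDataError("AUC requires both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def evaluate(scores, labels, threshold: float) -> EvalResult:
    """Full evaluation at a fixed threshold, including AUC."""
    cc = confusion(scores, labels, threshold)
    res = metrics(cc, threshold=threshold)
    return EvalResult(**{**res.to_dict(), "auc": auc(scores, labels)})


def mtss_threshold(scores, labels) -> tuple[float, EvalResult]:
    """Maximum-sensitivity-plus-specificity threshold and the metrics there.

    Candidates are the unique observed scores plus the endpoints 0 and 1;
    among maximizers the lowest threshold is returned.
    """
    scores, labels = _check_scores_labels(scores, labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise EmptyDataError("MTSS requires both classes")
    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    # scores are probabilities; keep candidates in [0,1]
    candidates = candidates[(candidates >= 0.0) & (candidates <= 1.0)]
    best_thr, best_tss = candidates[0], -np.inf
    for thr in candidates:
        pred = scores >= thr
        sens = (pred & pos).sum() / n1
        spec = (~pred & ~pos).sum() / n0
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-15:  # strict improvement keeps the lowest tie
            best_thr, best_tss = float(thr), float(tss)
    return best_thr, evaluate(scores, labels, best_thr)


def replicate_summary(results: list[EvalResult]) -> dict[str, dict[str, float]]:
    """Mean ± SD across replicate evaluations (report-style aggregation)."""
    if not results:
        raise EmptyDataError("no replicate results")
    out: dict[str, dict[str, float]] = {}
    for key in ("threshold", "sensitivity", "specificity", "tss", "kappa", "overall_accuracy", "auc"):
        vals = np.array([getattr(r, key) for r in results], float)
        out[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return out
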