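"""Presence/background assembly, 70/30 splits, and the four member algorithms.

The members are the classical SDM quartet behind one train/predict surface:

* GLM — binomial regression with a logit link on linear terms (statsmodels);
* RF — 500-tree random-forest classifier, prediction = class-1 vote fraction;
* BRT — stochastic gradient-boosted trees with logistic loss, slow learning
  rate (0.01), depth-3 trees, tree count chosen by internal validation when
  the training set is large enough to hold one out;
* SVM — RBF-kernel support vector classifier with Platt-scaled probabilities.

All predictions are probabilities in [0,1].  Background (pseudo-absence)
points are drawn uniformly from non-nodata cells that hold no presence, a
deliberately simple stand-in for the unreported background schemes of typical
field studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import EmptyDataError, FitError
from .raster_io import EnvStack, OccurrenceSet

ALGORITHMS = ("glm", "rf", "brt", "svm")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "glm": {"quadratic": True},
    "rf": {"n_estimators": 500},
    "brt": {
        "learning_rate": 0.01,
        "max_depth": 3,
        "n_estimators": 1000,
        "subsample": 0.75,
        "validation_fraction": 0.2,
        "n_iter_no_change": 25,
    },
    "svm": {"kernel": "rbf", "C": 1.0},
}

#: below this many training rows the BRT holds nothing out and uses a fixed
#: tree count instead of early stopping
_MIN_ROWS_FOR_VALIDATION = 50


def make_background(
    stack: EnvStack,
    occ: OccurrenceSet,
    n_background: int | None = None,
    seed: int | np.random.Generator = 0,
) -> OccurrenceSet:
    """Append uniformly drawn background points to the presences.

    Background cells are sampled without replacement from non-nodata cells not
    containing a presence; points sit at cell centers.  Default size is
    min(1000, 10 × presences), capped by the number of eligible cells.
    Duplicate presences within one cell are collapsed first (standard thinning).
    """
    t = stack.transform
    pres = occ.points[occ.points["label"] == "presence"]
    row, col = t.xy_to_rowcol(pres["x"].to_numpy(), pres["y"].to_numpy())
    nrows, ncols = stack.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    if not inside.all():
        raise ValueError(f"{(~inside).sum()} presence point(s) outside the stack extent")
    pres_cells = np.unique(row * ncols + col)
    # thinned presences, one per occupied cell, at cell centers
    prow, pcol = np.divmod(pres_cells, ncols)
    px, py = t.cell_center(prow, pcol)

    if n_background is None:
        n_background = min(1000, 10 * len(pres_cells))
    if n_background < 1:
        raise ValueError("n_background must be >= 1")
    eligible = np.flatnonzero(~stack.nodata_mask.ravel())
    eligible = np.setdiff1d(eligible, pres_cells, assume_unique=True)
    if n_background > eligible.size:
        raise EmptyDataError(
            f"n_background={n_background} exceeds the {eligible.size} eligible cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_background, replace=False)
    chosen.sort()
    brow, bcol = np.divmod(chosen, ncols)
    bx, by = t.cell_center(brow, bcol)
    pts = pd.DataFrame(
        {
            "x": np.concatenate([px, bx]),
            "y": np.concatenate([py, by]),
            "label": ["presence"] * len(px) + ["background"] * len(bx),
        }
    )
    return OccurrenceSet(species=occ.species, points=pts)


@dataclass
class SDMDataset:
    """Feature rows with labels and a stratified train/test partition."""

    features: pd.DataFrame  # one column per retained variable
    labels: np.ndarray  # 1 = presence, 0 = background
    partition: np.ndarray  # "train" | "test"
    species: str = "unknown"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.features.to_numpy(float)).all():
            raise ValueError("features must be finite")
        for part in ("train", "test"):
            sel = self.partition == part
            if len(set(self.labels[sel])) < 2:
                raise EmptyDataError(f"{part} partition lacks one of the classes")

    @property
    def variables(self) -> list[str]:
        return list(self.features.columns)

    def part(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.partition == which
        return self.features.to_numpy(float)[sel], self.labels[sel]


def split(
    features: pd.DataFrame,
    labels: Sequence[int],
    train_frac: float = 0.7,
    seed: int | np.random.Generator = 0,
    species: str = "unknown",
) -> SDMDataset:
    """Stratified train/test split: ``train_frac`` of each class (rounded
    half-up) goes to training; e.g. 56 presences at 0.7 → 39 train / 17 test."""
    labels = np.asarray(labels, int)
    if len(features) != len(labels):
        raise ValueError("features and labels must have equal length")
    if len(labels) < 10:
        raise EmptyDataError("need at least 10 rows to split")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    partition = np.empty(len(labels), object)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise EmptyDataError(f"class {cls} has fewer than 2 rows")
        n_train = int(np.floor(train_frac * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)  # both partitions non-empty
        perm = rng.permutation(idx)
        partition[perm[:n_train]] = "train"
        partition[perm[n_train:]] = "test"
    return SDMDataset(
        features=features.reset_index(drop=True),
        labels=labels,
        partition=partition.astype(str),
        species=species,
    )


@dataclass
class FittedModel:
    """A fitted member algorithm; ``predict`` maps feature rows to [0,1]."""

    algorithm: str
    variables: list[str]
    estimator: object = field(repr=False)
    seed: int | None = None
    replicate: int | None = None
    glm_quadratic: bool = False

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.variables].to_numpy(float)
        X = np.asarray(X, float)
        if self.algorithm == "glm":
            if self.glm_quadratic:
                X = np.column_stack([X, X**2])
            p = np.asarray(self.estimator.predict(sm.add_constant(X, has_constant="add")))
        else:
            p = self.estimator.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)

    def predict_map(self, stack: EnvStack) -> np.ndarray:
        return predict_map(self, stack)


def fit(
    algorithm: str,
    X_train: np.ndarray | pd.DataFrame,
    y_train: Sequence[int],
    variables: Sequence[str] | None = None,
    hyperparameters: Mapping | None = None,
    seed: int = 0,
    replicate: int | None = None,
) -> FittedModel:
    """Fit one member algorithm; see module docstring for the defaults."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if isinstance(X_train, pd.DataFrame):
        variables = list(X_train.columns)
        X_train = X_train.to_numpy(float)
    else:
        X_train = np.asarray(X_train, float)
        if variables is None:
            variables = [f"x{i}" for i in range(X_train.shape[1])]
    y = np.asarray(y_train, int)
    if len(set(y)) < 2:
        raise EmptyDataError("training set must contain both classes")
    hp = dict(DEFAULT_HYPERPARAMETERS[algorithm])
    hp.update(hyperparameters or {})
    glm_quadratic = bool(hp.pop("quadratic", False)) if algorithm == "glm" else False
    try:
        if algorithm == "glm":
            # linear + quadratic terms: lets the binomial GLM express the
            # unimodal (bell-shaped) responses typical of environmental niches
            X_design = np.column_stack([X_train, X_train**2]) if glm_quadratic else X_train
            model = sm.GLM(y, sm.add_constant(X_design, has_constant="add"),
                           family=sm.families.Binomial())
            with warnings.catch_warnings():
                # separable training data saturates the logit; predictions
                # remain valid probabilities, so this is not an error here
                warnings.filterwarnings("ignore", message=".*[Pp]erfect separation.*")
                warnings.filterwarnings("ignore", category=RuntimeWarning)
                est = model.fit(**hp)
        elif algorithm == "rf":
            est = RandomForestClassifier(random_state=seed, **hp).fit(X_train, y)
        elif algorithm == "brt":
            if len(y) < _MIN_ROWS_FOR_VALIDATION:
                for k in ("validation_fraction", "n_iter_no_change"):
                    hp.pop(k, None)
                hp["n_estimators"] = min(hp.get("n_estimators", 1000), 500)
            est = GradientBoostingClassifier(random_state=seed, **hp).fit(X_train, y)
        else:  # svm: margin classifier with Platt-scaled probabilities
            est = make_pipeline(
                StandardScaler(),
                CalibratedClassifierCV(
                    SVC(random_state=seed, **hp), method="sigmoid", ensemble=False
                ),
            ).fit(X_train, y)
    except EmptyDataError:
        raise
    except Exception as exc:  # propagate with algorithm diagnostics
        raise FitError(f"{algorithm} failed to fit: {exc!r}") from exc
    return FittedModel(
        algorithm=algorithm, variables=list(variables), estimator=est, seed=seed,
        replicate=replicate, glm_quadratic=glm_quadratic,
    )


@dataclass
class AveragedModel:
    """Mean prediction over replicate fits of one algorithm (same variables)."""

    algorithm: str
    models: list[FittedModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("AveragedModel needs at least one member fit")

    @property
    def variables(self) -> list[str]:
        return self.models[0].variables

    def predict(self, X) -> np.ndarray:
        return np.mean([m.predict(X) for m in self.models], axis=0)

    def predict_map(self, stack: EnvStack) -> np.ndarray:
        return predict_map(self, stack)


def predict_map(model: FittedModel | AveragedModel, stack: EnvStack) -> np.ndarray:
    """Per-cell suitability in [0,1]; nodata cells are NaN in the output."""
    missing = [v for v in model.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing retained variable(s): {missing}")
    X, rows, cols = stack.to_table(model.variables)
    out = np.full(stack.shape, np.nan)
    out[rows, cols] = model.predict(X)
    return out
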