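"""Binary range maps, three-class suitability, change maps and km² accounting.

A continuous suitability map is converted to presence/absence at the MTSS
threshold (score ≥ threshold ⇒ suitable).  Range change between a current and
a future binary map is coded per cell as ``future×2 − current``:

====  =======  ======  ==========
code  current  future  meaning
====  =======  ======  ==========
 −1      1       0     loss
  0      0       0     unsuitable
  1      1       1     stable
  2      0       1     gain
====  =======  ======  ==========

Area accounting sums per-cell areas (km²) by class and enforces the internal
identities loss + stable = current suitable, gain + stable = future suitable,
and suitable + unsuitable = total, which every consistent change table must
satisfy.  Reported figures are rounded half-up to whole km² for display; raw
sums are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .exceptions import ConsistencyError, EmptyDataError

CHANGE_LEGEND = {-1: "loss", 0: "unsuitable", 1: "stable", 2: "gain"}


@dataclass
class BinaryMap:
    values: np.ndarray  # int8 {0,1}
    mask: np.ndarray  # True = nodata
    threshold: float
    scenario: str = "current"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0,1]")
        off = self.values[~self.mask]
        if off.size and not np.isin(off, (0, 1)).all():
            raise ValueError("binary map values must be 0 or 1 off-nodata")


@dataclass
class ChangeMap:
    codes: np.ndarray  # int8 {-1,0,1,2}
    mask: np.ndarray
    current_scenario: str
    future_scenario: str


def binarize(suitability: np.ndarray, threshold: float, scenario: str = "current") -> BinaryMap:
    """Presence/absence at the threshold; monotone: raising the threshold never
    turns a 0 cell into a 1."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0,1], got {threshold}")
    suit = np.asarray(suitability, float)
    mask = ~np.isfinite(suit)
    values = np.zeros(suit.shape, np.int8)
    values[~mask] = (suit[~mask] >= threshold).astype(np.int8)
    return BinaryMap(values=values, mask=mask, threshold=threshold, scenario=scenario)


def classify_suitability(
    suitability: np.ndarray, boundaries: tuple[float, float] = (1 / 3, 2 / 3)
) -> np.ndarray:
    """Three suitability classes: low = [0,b1), medium = [b1,b2), high = [b2,1].

    Returns an int8 grid (0/1/2) with −1 at nodata.
    """
    b1, b2 = boundaries
    if not 0.0 < b1 < b2 < 1.0:
        raise ValueError(f"boundaries must satisfy 0 < b1 < b2 < 1, got {boundaries}")
    suit = np.asarray(suitability, float)
    mask = ~np.isfinite(suit)
    out = np.full(suit.shape, -1, np.int8)
    v = suit[~mask]
    out[~mask] = np.where(v >= b2, 2, np.where(v >= b1, 1, 0)).astype(np.int8)
    return out


def change_map(current: BinaryMap, future: BinaryMap) -> ChangeMap:
    """Per-cell code = future×2 − current (see module table)."""
    if current.values.shape != future.values.shape:
        raise ValueError("current and future maps must share the grid")
    if not np.array_equal(current.mask, future.mask):
        raise ValueError("current and future maps must share the nodata mask")
    codes = (future.values.astype(np.int8) * 2 - current.values.astype(np.int8))
    codes = codes.copy()
    codes[current.mask] = np.int8(-128)  # sentinel under the mask, never reported
    return ChangeMap(
        codes=codes,
        mask=current.mask.copy(),
        current_scenario=current.scenario,
        future_scenario=future.scenario,
    )


@dataclass
class AreaSummary:
    """Per-class areas in km² plus the total over all non-nodata cells."""

    class_km2: dict[str, float]
    total_km2: float

    def rounded(self) -> dict[str, int]:
        out = {k: _round_half_up(v) for k, v in self.class_km2.items()}
        out["total"] = _round_half_up(self.total_km2)
        return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _cell_area_grid(shape: tuple[int, int], cell_areas) -> np.ndarray:
    areas = np.asarray(cell_areas, float)
    if areas.ndim == 0:
        return np.full(shape, float(areas))
    if areas.ndim == 1:  # per-latitude-row
        if areas.size != shape[0]:
            raise ValueError("per-row cell areas must match the number of rows")
        return np.repeat(areas[:, None], shape[1], axis=1)
    if areas.shape != shape:
        raise ValueError("cell-area grid must match the map shape")
    return areas


def area_summary(m: BinaryMap | ChangeMap, cell_areas) -> AreaSummary:
    """Σ cell areas per class; ``cell_areas`` is a scalar, a per-row vector
    (as from :func:`esdm.raster_io.cell_area_km2`) or a full grid, in km²."""
    if isinstance(m, BinaryMap):
        grid, mask = m.values, m.mask
        classes = {0: "unsuitable", 1: "suitable"}
    else:
        grid, mask = m.codes, m.mask
        classes = CHANGE_LEGEND
    if mask.all():
        raise EmptyDataError("map has no non-nodata cells")
    areas = _cell_area_grid(grid.shape, cell_areas)
    valid = ~mask
    per_class = {
        name: float(areas[valid & (grid == code)].sum()) for code, name in classes.items()
    }
    return AreaSummary(class_km2=per_class, total_km2=float(areas[valid].sum()))


def change_report(
    current: BinaryMap,
    futures: Mapping[str, BinaryMap],
    cell_areas,
) -> dict:
    """Scenario table of suitable/unsuitable and loss/stable/gain areas (km²).

    The accounting identities are asserted before emission; a violation
    indicates a threshold or mask bug and raises :class:`ConsistencyError`.
    """
    cur_sum = area_summary(current, cell_areas)
    report: dict = {
        "current": {
            "suitable_km2": cur_sum.class_km2["suitable"],
            "unsuitable_km2": cur_sum.class_km2["unsuitable"],
            "total_km2": cur_sum.total_km2,
        },
        "scenarios": {},
    }
    tol = 1e-6 * max(cur_sum.total_km2, 1.0)
    if abs(cur_sum.class_km2["suitable"] + cur_sum.class_km2["unsuitable"] - cur_sum.total_km2) > tol:
        raise ConsistencyError("current map: suitable + unsuitable != total")
    for name, future in futures.items():
        fut_sum = area_summary(future, cell_areas)
        cm = change_map(current, future)
        ch = area_summary(cm, cell_areas)
        loss, stable, gain = (ch.class_km2[k] for k in ("loss", "stable", "gain"))
        if abs(loss + stable - cur_sum.class_km2["suitable"]) > tol:
            raise ConsistencyError(f"{name}: loss + stable != current suitable")
        if abs(gain + stable - fut_sum.class_km2["suitable"]) > tol:
            raise ConsistencyError(f"{name}: gain + stable != future suitable")
        if abs(fut_sum.class_km2["suitable"] + fut_sum.class_km2["unsuitable"] - fut_sum.total_km2) > tol:
            raise ConsistencyError(f"{name}: suitable + unsuitable != total")
        report["scenarios"][name] = {
            "suitable_km2": fut_sum.class_km2["suitable"],
            "unsuitable_km2": fut_sum.class_km2["unsuitable"],
            "loss_km2": loss,
            "stable_km2": stable,
            "gain_km2": gain,
            "never_suitable_km2": ch.class_km2["unsuitable"],
            "total_km2": fut_sum.total_km2,
        }
    return report
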