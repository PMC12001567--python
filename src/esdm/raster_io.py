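"""Raster stacks, occurrence tables and the cell-area basis for km² accounting.

Rasters are exchanged as single-band ESRI ASCII grids (``.asc``) — the plain-text
raster format used throughout the SDM ecosystem — with square cells and nodata
encoded via the ``NODATA_value`` header field.  All layers of a stack must be
pre-aligned (identical shape, origin and cell size); reprojection and resampling
are out of scope.

Coordinate conventions: a north-up grid with ``x = x_origin + col*dx`` (west edge)
and ``y = y_origin - row*dy`` (north edge).  Cell membership is half-open,
``[x0, x0+dx) × (y0-dy, y0]``: a point on a vertical cell edge belongs to the cell
to its right, a point on a horizontal edge to the cell below.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, EmptyDataError, FormatError

logger = logging.getLogger(__name__)

#: mean Earth radius [km] used for spherical cell areas
EARTH_RADIUS_KM = 6371.0088

_GEOGRAPHIC = "geographic"
_PROJECTED = "projected"


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeferencing: origin is the top-left corner of cell (0,0)."""

    x_origin: float
    y_origin: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError(f"cell size must be strictly positive, got dx={self.dx}, dy={self.dy}")

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) under the half-open cell convention."""
        col = np.floor((np.asarray(x, float) - self.x_origin) / self.dx).astype(int)
        row = np.floor((self.y_origin - np.asarray(y, float)) / self.dy).astype(int)
        return row, col

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.x_origin + (np.asarray(col) + 0.5) * self.dx
        y = self.y_origin - (np.asarray(row) + 0.5) * self.dy
        return x, y

    def close_to(self, other: "GridTransform", tol: float = 1e-9) -> bool:
        return (
            abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass
class EnvStack:
    """Named, co-registered environmental layers with a shared nodata mask.

    ``layers`` maps layer name to a 2-D float array in which nodata cells hold
    NaN; ``nodata_mask`` is True exactly where any layer is nodata (union mask).
    ``crs`` is ``"geographic"`` (degrees, WGS84-style) or ``"projected"``
    (meters); anything else forces the caller to supply explicit cell areas.
    """

    layers: dict[str, np.ndarray]
    transform: GridTransform
    crs: str = _GEOGRAPHIC
    units: dict[str, str] = field(default_factory=dict)
    nodata_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvStack requires at least one layer")
        shapes = {name: arr.shape for name, arr in self.layers.items()}
        if len(set(shapes.values())) != 1:
            raise AlignmentError(f"layers differ in shape: {shapes}")
        union = np.zeros(self.shape, bool)
        for arr in self.layers.values():
            union |= ~np.isfinite(arr)
        if self.nodata_mask is None:
            self.nodata_mask = union
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, bool) | union
        for arr in self.layers.values():
            arr[self.nodata_mask] = np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def subset(self, names: Sequence[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(
            layers={n: self.layers[n].copy() for n in names},
            transform=self.transform,
            crs=self.crs,
            units={n: self.units[n] for n in names if n in self.units},
            nodata_mask=self.nodata_mask.copy(),
        )

    def to_table(self, names: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten valid cells to a feature matrix: (values (n_valid, p), rows, cols)."""
        names = list(names) if names is not None else self.layer_names
        rows, cols = np.nonzero(~self.nodata_mask)
        X = np.column_stack([self.layers[n][rows, cols] for n in names])
        return X, rows, cols


@dataclass
class OccurrenceSet:
    """Labeled presence/background points for one species (WGS84-style x/y)."""

    species: str
    points: pd.DataFrame  # columns: x, y, label in {"presence", "background"}

    def __post_init__(self) -> None:
        required = {"x", "y", "label"}
        if not required.issubset(self.points.columns):
            raise FormatError(f"points table needs columns {sorted(required)}")
        bad = set(self.points["label"]) - {"presence", "background"}
        if bad:
            raise FormatError(f"unknown labels: {sorted(bad)}")
        if (self.points["label"] == "presence").sum() < 1:
            raise EmptyDataError(f"no presence points for species {self.species!r}")

    @property
    def n_presence(self) -> int:
        return int((self.points["label"] == "presence").sum())

    @property
    def n_background(self) -> int:
        return int((self.points["label"] == "background").sum())


# ---------------------------------------------------------------------------
# ESRI ASCII grid reader / writer

def _read_asc(path: Path) -> tuple[np.ndarray, GridTransform]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0][:1].isalpha():
                try:
                    header[parts[0].lower()] = float(parts[1])
                except ValueError as exc:
                    raise FormatError(f"{path}: bad header line {line!r}") from exc
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        try:
            grid = np.loadtxt(fh, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed grid body ({exc})") from exc
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing ASCII-grid header field {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if grid.shape != (nrows, ncols):
        raise FormatError(f"{path}: body shape {grid.shape} != header ({nrows}, {ncols})")
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0 = header["xllcorner"]
        y_top = header["yllcorner"] + nrows * cell
    elif "xllcenter" in header:
        x0 = header["xllcenter"] - cell / 2
        y_top = header["yllcenter"] - cell / 2 + nrows * cell
    else:
        raise FormatError(f"{path}: missing xllcorner/xllcenter header field")
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid[grid == nodata] = np.nan
    return grid, GridTransform(x0, y_top, cell, cell)


def _write_asc(path: Path, grid: np.ndarray, transform: GridTransform, nodata: float = -9999.0) -> None:
    if abs(transform.dx - transform.dy) > 1e-12:
        raise FormatError("ASCII grids require square cells")
    nrows, ncols = grid.shape
    out = np.where(np.isfinite(grid), grid, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {transform.x_origin!r}\n")
        fh.write(f"yllcorner {(transform.y_origin - nrows * transform.dy)!r}\n")
        fh.write(f"cellsize {transform.dx!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_stack(
    paths: Sequence[str | Path],
    names: Sequence[str] | None = None,
    crs: str = _GEOGRAPHIC,
    units: Mapping[str, str] | None = None,
) -> EnvStack:
    """Read co-registered single-band ASCII-grid rasters into an :class:`EnvStack`.

    The nodata mask of the returned stack is the union over all input layers.
    Raises :class:`AlignmentError` naming the offending file on any shape or
    georeferencing mismatch, and ``ValueError`` on duplicate layer names.
    """
    paths = [Path(p) for p in paths]
    if names is None:
        names = [p.stem for p in paths]
    if len(names) != len(paths):
        raise ValueError("names and paths must have equal length")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if list(names).count(n) > 1})
        raise ValueError(f"duplicate layer names: {dupes}")
    layers: dict[str, np.ndarray] = {}
    ref_transform: GridTransform | None = None
    ref_shape = None
    for name, path in zip(names, paths):
        grid, transform = _read_asc(path)
        if ref_transform is None:
            ref_transform, ref_shape = transform, grid.shape
        else:
            if grid.shape != ref_shape:
                raise AlignmentError(
                    f"{path}: shape {grid.shape} does not match first raster {ref_shape}"
                )
            if not transform.close_to(ref_transform):
                raise AlignmentError(f"{path}: georeferencing does not match first raster")
        layers[name] = grid
    return EnvStack(layers=layers, transform=ref_transform, crs=crs, units=dict(units or {}))


def write_stack(stack: EnvStack, directory: str | Path, nodata: float = -9999.0) -> list[Path]:
    """Write each layer as ``<directory>/<name>.asc``; round-trips bit-exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, grid in stack.layers.items():
        path = directory / f"{name}.asc"
        _write_asc(path, grid, stack.transform, nodata=nodata)
        written.append(path)
    return written


def write_grid(path: str | Path, grid: np.ndarray, transform: GridTransform, nodata: float = -9999.0) -> None:
    """Write a single 2-D grid (NaN = nodata) as an ASCII-grid raster."""
    _write_asc(Path(path), np.asarray(grid, float), transform, nodata=nodata)


# ---------------------------------------------------------------------------
# Occurrences

def read_occurrences(path: str | Path, species: str) -> OccurrenceSet:
    """Read a GBIF-style CSV (columns ``species,lon,lat``) filtered to one species."""
    df = pd.read_csv(path)
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    sub = df[df["species"] == species]
    if len(sub) == 0:
        raise EmptyDataError(f"no rows for species {species!r} in {path}")
    pts = pd.DataFrame(
        {"x": sub["lon"].to_numpy(float), "y": sub["lat"].to_numpy(float), "label": "presence"}
    )
    return OccurrenceSet(species=species, points=pts)


def write_occurrences(path: str | Path, occ: OccurrenceSet) -> None:
    presences = occ.points[occ.points["label"] == "presence"]
    pd.DataFrame(
        {"species": occ.species, "lon": presences["x"], "lat": presences["y"]}
    ).to_csv(path, index=False)


def extract_features(stack: EnvStack, occ: OccurrenceSet) -> pd.DataFrame:
    """One row per point with the layer values of the containing cell.

    Points landing on nodata cells are dropped (count logged at INFO).  Raises
    :class:`EmptyDataError` if nothing survives.  Output columns: ``x``, ``y``,
    ``label``, ``row``, ``col``, then one column per layer.
    """
    x = occ.points["x"].to_numpy(float)
    y = occ.points["y"].to_numpy(float)
    row, col = stack.transform.xy_to_rowcol(x, y)
    nrows, ncols = stack.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    if not inside.all():
        raise ValueError(f"{(~inside).sum()} point(s) fall outside the stack extent")
    on_data = ~stack.nodata_mask[row, col]
    n_dropped = int((~on_data).sum())
    if n_dropped:
        logger.info("extract_features: dropped %d point(s) on nodata cells", n_dropped)
    if not on_data.any():
        raise EmptyDataError("all points fall on nodata cells")
    row, col = row[on_data], col[on_data]
    out = pd.DataFrame(
        {
            "x": x[on_data],
            "y": y[on_data],
            "label": occ.points["label"].to_numpy()[on_data],
            "row": row,
            "col": col,
        }
    )
    for name, grid in stack.layers.items():
        out[name] = grid[row, col]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cell areas

def cell_area_km2(stack: EnvStack) -> np.ndarray:
    """Per-latitude-row cell area in km², shape ``(nrows,)``.

    Projected grids (cell size in meters) give a constant |dx·dy| per cell.
    Geographic grids use the exact spherical band area
    ``R² · dλ · (sin φ_top − sin φ_bottom)`` per row, R = 6371.0088 km.
    """
    t = stack.transform
    nrows = stack.shape[0]
    if stack.crs == _PROJECTED:
        return np.full(nrows, t.dx * t.dy / 1e6)
    if stack.crs == _GEOGRAPHIC:
        i = np.arange(nrows)
        phi_top = np.radians(t.y_origin - i * t.dy)
        phi_bot = np.radians(t.y_origin - (i + 1) * t.dy)
        dlam = math.radians(t.dx)
        return EARTH_RADIUS_KM**2 * dlam * (np.sin(phi_top) - np.sin(phi_bot))
    raise ValueError(
        f"unknown CRS {stack.crs!r}: supply 'geographic' or 'projected', "
        "or provide an explicit cell-area override"
    )


def total_area_km2(stack: EnvStack) -> float:
    """Σ cell area over non-nodata cells; invariant under layer reordering."""
    per_row = cell_area_km2(stack)
    valid_per_row = (~stack.nodata_mask).sum(axis=1)
    return float((per_row * valid_per_row).sum())
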