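"""Virtual landscapes and virtual species with known response functions.

The generator builds spatially autocorrelated, cross-correlated environmental
layers, defines a species whose true suitability is a known function of a
subset of those layers (unimodal Gaussian or monotone logistic responses),
samples presence points proportionally to suitability, and produces shifted
"future" layer stacks emulating emission-scenario climate change.  Because the
generative truth is known, every downstream stage — collinearity screening,
model fitting, ensembling, thresholding, change accounting, importance and
response-curve recovery — can be validated by parameter recovery instead of
field data.

Spatial fields are made by Gaussian-kernel smoothing of white noise; the target
cross-layer correlation is then imposed exactly by empirically orthonormalising
the smoothed fields (QR decomposition over cells) and mixing them with the
Cholesky factor of the target correlation matrix.  Layers are standardized to
zero mean and unit variance over the grid, so response parameters and scenario
shifts are expressed in SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import EmptyDataError
from .raster_io import EnvStack, GridTransform, OccurrenceSet

Shape = Literal["gaussian", "logistic", "linear"]
CombinationRule = Literal["product", "additive-logistic"]


@dataclass(frozen=True)
class Response:
    """One variable's contribution to true suitability.

    gaussian: exp(−(v−loc)²/(2·scale²)) — unimodal, optimum at ``loc``.
    logistic: 1/(1+exp(−(v−loc)/scale)) — monotone, midpoint at ``loc``;
              negative ``scale`` gives a decreasing response.
    linear:   clip(scale·v + loc, 0, 1).
    """

    variable: str
    shape: Shape
    loc: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.shape == "gaussian" and not self.scale > 0:
            raise ValueError("gaussian response requires scale > 0")
        if self.shape == "logistic" and self.scale == 0:
            raise ValueError("logistic response requires scale != 0")

    def __call__(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, float)
        if self.shape == "gaussian":
            return np.exp(-((v - self.loc) ** 2) / (2 * self.scale**2))
        if self.shape == "logistic":
            return 1.0 / (1.0 + np.exp(-(v - self.loc) / self.scale))
        return np.clip(self.scale * v + self.loc, 0.0, 1.0)


@dataclass
class VirtualSpecies:
    """A species with known responses and a deterministic true-suitability map."""

    responses: list[Response]
    true_suitability: np.ndarray  # 2-D, in [0,1], NaN on nodata
    combination_rule: CombinationRule
    stack: EnvStack = field(repr=False)


def make_stack(
    shape: tuple[int, int],
    n_layers: int,
    correlation: np.ndarray | None = None,
    autocorr_range: float = 5.0,
    seed: int | np.random.Generator = 0,
    names: Sequence[str] | None = None,
    transform: GridTransform | None = None,
    crs: str = "geographic",
) -> EnvStack:
    """Generate standardized, spatially smooth, cross-correlated layers.

    ``correlation`` is the target pairwise correlation matrix (default
    identity); it must be symmetric positive-definite with unit diagonal.  The
    empirical correlation of the generated layers matches the target to
    numerical precision because the underlying fields are orthonormalised
    before mixing.  Requires more cells than layers.
    """
    nrows, ncols = shape
    n_cells = nrows * ncols
    if n_cells <= max(n_layers, 1):
        raise ValueError(
            f"insufficient cells ({n_cells}) for correlation control over {n_layers} layers"
        )
    rng = np.random.default_rng(seed)
    if correlation is None:
        correlation = np.eye(n_layers)
    correlation = np.asarray(correlation, float)
    if correlation.shape != (n_layers, n_layers):
        raise ValueError("correlation matrix shape must be (n_layers, n_layers)")
    if not np.allclose(correlation, correlation.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(correlation), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")
    try:
        L = np.linalg.cholesky(correlation)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix must be positive-definite") from exc

    fields = np.empty((n_cells, n_layers))
    for j in range(n_layers):
        noise = rng.standard_normal((nrows, ncols))
        smooth = gaussian_filter(noise, sigma=autocorr_range, mode="reflect")
        fields[:, j] = smooth.ravel()
    fields -= fields.mean(axis=0)
    # Orthonormalise over cells, fix QR sign for seed stability, then mix.
    Q, R = np.linalg.qr(fields)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    mixed = Q @ L.T
    mixed /= mixed.std(axis=0)

    if names is None:
        names = [f"env{j + 1}" for j in range(n_layers)]
    if transform is None:
        # 30-arc-second cells (the usual ~1 km climate-grid resolution) in a
        # mid-latitude window, so spherical cell areas are realistic
        transform = GridTransform(33.5, 28.9, 1.0 / 120.0, 1.0 / 120.0)
    layers = {name: mixed[:, j].reshape(nrows, ncols) for j, name in enumerate(names)}
    return EnvStack(layers=layers, transform=transform, crs=crs)


def true_suitability(
    stack: EnvStack,
    responses: Sequence[Response],
    rule: CombinationRule = "product",
) -> VirtualSpecies:
    """Evaluate the known response functions on the stack and combine them.

    ``product`` multiplies the per-variable responses (a zero anywhere is
    absorbing); ``additive-logistic`` sums the responses on the logit scale and
    maps back through the logistic.  The result is clamped to [0,1] and NaN on
    nodata cells.
    """
    missing = [r.variable for r in responses if r.variable not in stack.layers]
    if missing:
        raise KeyError(f"response variables not in stack: {missing}")
    parts = [r(stack.layers[r.variable]) for r in responses]
    if rule == "product":
        suit = np.prod(parts, axis=0)
    elif rule == "additive-logistic":
        eps = 1e-12
        z = sum(np.log(np.clip(p, eps, 1 - eps) / (1 - np.clip(p, eps, 1 - eps))) for p in parts)
        suit = 1.0 / (1.0 + np.exp(-z / len(parts)))
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    suit = np.clip(suit, 0.0, 1.0)
    suit[stack.nodata_mask] = np.nan
    return VirtualSpecies(
        responses=list(responses), true_suitability=suit, combination_rule=rule, stack=stack
    )


def sample_presences(
    vs: VirtualSpecies,
    n_presence: int,
    seed: int | np.random.Generator = 0,
    species: str = "virtual",
) -> OccurrenceSet:
    """Draw presence cells without replacement, probability ∝ true suitability.

    One presence per drawn cell, placed at the cell center, so feature
    extraction recovers the generating layer values exactly.
    """
    if n_presence < 1:
        raise EmptyDataError("n_presence must be >= 1")
    suit = vs.true_suitability
    valid = np.isfinite(suit) & (suit > 0)
    n_eligible = int(valid.sum())
    if n_presence > n_eligible:
        raise ValueError(
            f"n_presence={n_presence} exceeds the {n_eligible} cells with positive suitability"
        )
    rng = np.random.default_rng(seed)
    flat_idx = np.flatnonzero(valid.ravel())
    probs = suit.ravel()[flat_idx]
    chosen = rng.choice(flat_idx, size=n_presence, replace=False, p=probs / probs.sum())
    chosen.sort()
    nrows, ncols = suit.shape
    rows, cols = np.divmod(chosen, ncols)
    x, y = vs.stack.transform.cell_center(rows, cols)
    pts = pd.DataFrame({"x": x, "y": y, "label": "presence"})
    return OccurrenceSet(species=species, points=pts)


def make_future(stack: EnvStack, shifts: Mapping[str, float]) -> EnvStack:
    """Additively shift named layers (scenario deltas in layer units).

    Unshifted layers are copied; the nodata mask is unchanged.  Applying the
    opposite shifts restores the original stack bit-exactly.
    """
    unknown = [k for k in shifts if k not in stack.layers]
    if unknown:
        raise KeyError(f"shift keys not in stack: {unknown}")
    layers = {}
    for name, grid in stack.layers.items():
        delta = shifts.get(name, 0.0)
        layers[name] = grid + delta if delta != 0.0 else grid.copy()
    return EnvStack(
        layers=layers,
        transform=stack.transform,
        crs=stack.crs,
        units=dict(stack.units),
        nodata_mask=stack.nodata_mask.copy(),
    )


# ---------------------------------------------------------------------------
# Default virtual-species fixture

#: layer roles in the default fixture
FIXTURE_LAYERS = ("env1", "env2", "env3", "env4", "env5", "env6")
FIXTURE_CAUSAL = ("env1", "env2")
FIXTURE_DECOYS = ("env3", "env4")  # r ≈ 0.9 with the causal pair
FIXTURE_NOISE = ("env5", "env6")
#: narrow niches centered off the field mean (±1.25 SD, width 0.5 SD): the
#: virtual species favors the upper/lower reaches of its two causal gradients,
#: like a mountain endemic, giving strong presence/background contrast while
#: keeping both optima inside the sampled environmental range
FIXTURE_RESPONSES = (
    Response("env1", "gaussian", loc=1.25, scale=0.5),
    Response("env2", "gaussian", loc=-1.25, scale=0.5),
)


def fixture_correlation(r_decoy: float = 0.9) -> np.ndarray:
    corr = np.eye(6)
    corr[0, 2] = corr[2, 0] = r_decoy  # env3 tracks env1
    corr[1, 3] = corr[3, 1] = r_decoy  # env4 tracks env2
    return corr


def default_fixture(
    seed: int = 0,
    shape: tuple[int, int] = (100, 100),
    n_presence: int = 150,
    autocorr_range: float = 5.0,
    species: str = "virtual",
) -> tuple[EnvStack, VirtualSpecies, OccurrenceSet]:
    """The standard test landscape: 100×100 grid, 6 layers (2 causal Gaussian
    responses, 2 decoys correlated at r≈0.9 with the causal pair, 2 noise),
    150 presences — mirroring the scale of small endemic-species datasets."""
    ss = np.random.SeedSequence(seed)
    stack_rng, pres_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    stack = make_stack(
        shape,
        n_layers=6,
        correlation=fixture_correlation(),
        autocorr_range=autocorr_range,
        seed=stack_rng,
        names=FIXTURE_LAYERS,
    )
    vs = true_suitability(stack, FIXTURE_RESPONSES, rule="product")
    occ = sample_presences(vs, n_presence, seed=pres_rng, species=species)
    return stack, vs, occ
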