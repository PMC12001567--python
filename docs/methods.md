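# Methods

This note records the models, conventions and numerical choices behind `esdm`,
in the order the pipeline applies them, together with what the synthetic
landscape does and does not emulate.

## Data model and raster conventions

An environmental stack is an ordered set of named 2-D layers sharing one grid:
identical shape, north-up affine transform (west-edge/north-edge origin,
strictly positive cell size) and a single **union** nodata mask — a cell masked
in any layer is masked in all, so every downstream feature vector is complete.
Rasters are read and written as single-band ESRI ASCII grids with square cells;
values are stored at full double precision (`repr`), so write→read round-trips
are bit-exact for finite cells.  Reprojection and resampling are out of scope:
inputs must arrive co-registered.

Cell membership is half-open, `[x0, x0+dx) × (y0−dy, y0]`: a point on a
vertical cell edge belongs to the cell to its right, on a horizontal edge to
the cell below.  This makes point→cell assignment deterministic and matches
common raster-sampling behaviour.

Cell areas, the basis of every km² figure, are computed per latitude row on the
sphere: `R² · dλ · (sin φ_top − sin φ_bottom)` with R = 6371.0088 km.  This is
exact on the sphere and needs no projection machinery; projected grids (cell
size in meters) use the constant |dx·dy| instead.  Any other CRS must supply an
explicit override.  The spherical formula differs from the WGS84 ellipsoid by
well under 1 %, which is far below the thresholding variability that dominates
area estimates here.

## Collinearity screening

VIF_j = 1/(1 − R²_j), with R²_j from an ordinary least-squares regression of
column j on all other columns (plus intercept); exact linear dependence is
reported as infinite.  Two elimination procedures are offered:

* `vifstep`: repeatedly drop the max-VIF variable until all VIFs ≤ 5;
* `vifcor`: repeatedly find the pair with the largest |Pearson r|; while it
  exceeds 0.75, drop the member with the larger VIF; finish with a `vifstep`
  pass so the retained set also satisfies the VIF bound.  (The correlation
  rule alone bounds pairwise correlation but not VIF; the trailing pass makes
  the report's stated guarantee — every retained VIF ≤ threshold — true by
  construction.)

Ties (equal |r| or equal max VIF) are broken by column order of the input
table, making both procedures deterministic.  Features for screening are the
values at presence + background points — the same rows the models see — not
all raster cells.  Rows with any missing value are dropped first.  A single
surviving column is assigned VIF 1 by definition.

## Presence/background data and splits

True absences are unavailable in presence-only work, so background
(pseudo-absence) points are drawn uniformly at random, without replacement,
from non-nodata cells that contain no presence; duplicate presences within one
cell are collapsed first (standard thinning).  The default background size is
min(1000, 10 × presences).  This is a deliberately simple, fully disclosed
scheme; real studies often use bias-corrected or buffered backgrounds, which
are out of scope.

Train/test splits are stratified by class: 70 % of presences and 70 % of
backgrounds (rounded half-up, both partitions forced non-empty) go to
training.  With 56 presences this yields the 39/17 split that the round-half-up
rule implies.  Five replicate splits are the default; reported metrics are
replicate means ± SD.

## Member algorithms

All members expose `predict → probability in [0,1]`:

* **GLM** — binomial regression, logit link, linear **and quadratic** terms per
  predictor (statsmodels IRLS).  The quadratic terms let the parametric member
  express the unimodal, bell-shaped responses typical of environmental niches;
  a pure linear-logit model is monotone by construction and cannot place a
  suitability optimum inside a gradient.  `quadratic: false` restores the
  linear-only form.  Separation warnings during IRLS are suppressed: on
  separable data the fitted probabilities saturate, which is acceptable here.
* **RF** — 500-tree random-forest classifier; prediction is the class-1 vote
  fraction.
* **BRT** — stochastic gradient boosting (logistic loss, learning rate 0.01,
  depth-3 trees, subsample 0.75), up to 1000 trees with early stopping against
  a 20 % internal validation split; below 50 training rows the hold-out is
  skipped and a fixed 500 trees are used.
* **SVM** — RBF-kernel SVC on standardized features with Platt-scaled
  probabilities (`CalibratedClassifierCV`, sigmoid, single refit).

No class weighting is applied; sensitivity and specificity are prevalence-
insensitive, so the reported skill does not depend on the background size.
All hyperparameters are overridable per algorithm from the config.

## Evaluation

Confusion counts use the presence/absence layout a, b, c, d (rows = observed,
columns = predicted), with score ≥ threshold counting as predicted presence —
the boundary convention is fixed so counts are bit-reproducible.  Metrics are
the standard formulas: overall accuracy (a+d)/n, sensitivity a/(a+c),
specificity d/(b+d), TSS = sensitivity + specificity − 1, and Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) with p_e = ((a+b)(a+c)+(c+d)(b+d))/n².  AUC is the
rank-based (Mann–Whitney) form, ties counted half, hence invariant under any
strictly monotone rescaling of scores.

The MTSS threshold maximizes sensitivity + specificity over the candidate set
of unique observed scores plus the endpoints 0 and 1 — an exact maximization,
cheap at these sizes, rather than a fixed grid; ties resolve to the lowest
threshold, which favours sensitivity for rare species.

## Ensemble

Member weights are max(TSS_i, 0)/Σ max(TSS_j, 0): a below-chance member
contributes nothing rather than subtracting signal, and an ensemble with no
positive-TSS member is an error.  Each member's TSS is measured at its own
MTSS threshold on its test partition and averaged over replicates; the member
entering the ensemble map is the replicate-mean predictor (mean of the
replicate fits' predictions).  The ensemble prediction is the weighted mean,
hence bounded by the pointwise member min/max.

The ensemble's own MTSS threshold is recomputed from ensemble scores at all
presence/background rows (train + test pooled): the rule is a *training*
sensitivity-plus-specificity maximum, and because the ensemble averages models
trained on different 70 % subsets, no single held-out partition is canonical.
That one threshold, estimated under current climate, is reused for all future
projections rather than re-estimated per scenario.

## Projection and range change

Binary maps use score ≥ threshold.  Three-class suitability maps use
boundaries (1/3, 2/3) by default — low [0, b1), medium [b1, b2), high [b2, 1] —
configurable; no authoritative boundary values exist, so the choice is
surfaced in the report.  Range change is coded per cell as future×2 − current
(−1 loss, 0 never suitable, 1 stable, 2 gain).  Area accounting sums per-cell
spherical areas by class; the identities loss + stable = current suitable,
gain + stable = future suitable and suitable + unsuitable = total are asserted
(to 1e-6 relative) before any report is emitted, so a threshold or mask bug
surfaces as an error, not as a silently wrong table.  Reports carry raw
double-precision sums plus whole-km² half-up roundings for display.

## Importance and response curves

Permutation importance of variable v is the mean over permutations of
1 − corr(predictions on intact rows, predictions with v's column permuted),
clipped at 0, ×100.  It is deliberately unnormalized (values need not sum to
100), mirrors the correlation-based convention of the R SDM ecosystem, and an
AUC-drop variant is available for sensitivity analysis.  A variable the model
ignores scores exactly 0.

Response curves sweep one variable over its observed range (100-point grid)
with all other variables held at their data means (medians available).  Mean
conditioning on presence + background data places the profile in a
low-suitability region of the other gradients, so curve *levels* are modest;
the curve's *shape* and argmax are the recoverable quantities.

## The virtual landscape

`make_stack` smooths white noise with a Gaussian kernel (default range 5
cells), empirically orthonormalises the flattened fields (QR, with sign-fixed
diagonal for seed stability) and mixes them with the Cholesky factor of the
target correlation matrix, then standardizes: the generated layers carry the
target cross-correlations to numerical precision at any grid size, and layer
units are SD units.  The default georeference is a 30 arc-second window at
~28.5° N, so a 100×100 grid covers ≈ 7,547 km² — the scale of a mid-sized
protected area.

The default virtual species uses Gaussian responses at +1.25 SD (width 0.5 SD)
on `env1` and −1.25 SD on `env2`, combined by product; `env3`/`env4` are
decoys correlated at r = 0.9 with the causal pair, `env5`/`env6` pure noise;
150 presences are drawn without replacement with probability proportional to
true suitability and placed at cell centers (so feature extraction is exact).
The niche placement keeps both optima inside the sampled environmental range —
interior enough that an optimum is identifiable, eccentric enough that
presences contrast strongly with uniform background (every member algorithm
reaches test AUC well above 0.8).  Default scenario shifts move a causal layer
and its decoy together (+0.5 SD "low", +1.5 SD "high"), as co-varying climate
layers would under a real warming pathway.

What the generator does **not** emulate: sampling bias and detection error
(presences are an unbiased draw from suitability), non-stationary or
anisotropic spatial structure, interactions between predictors beyond the
response product, dispersal limitation, and scenario changes to spatial
pattern (shifts are spatially uniform).  Passing the recovery suite therefore
demonstrates correctness of the *machinery* — screening, fitting, weighting,
thresholding, accounting, explanation — not robustness to the observational
pathologies of real occurrence data.

## Reproducibility and problem sizes

A single global seed is expanded through `numpy.random.SeedSequence` into
independent per-stage streams (simulation, background, splits, fits,
permutations); all stochastic estimators receive derived integer seeds.  JSON
reports contain no timestamps, so identical configs reproduce identical bytes.
The shipped test suite and the acceptance script run the fixture at 100×100
cells with 150 presences and (in the test suite) 1–2 replicate splits per
configuration, sizes chosen so the complete validation executes in a few
minutes on one CPU while preserving the statistical behaviour the checks
probe; the pipeline default remains 5 replicates.

## Known limitations

* Background sampling is uniform; prevalence-dependent metrics (kappa, overall
  accuracy) therefore depend on the background size chosen.
* The GLM member's quadratic expansion is fixed rather than selected per
  variable; heavily skewed predictors may prefer other transforms.
* `vifcor`/`vifstep` decide between near-duplicate layers by VIF magnitude
  only; which member of a correlated pair survives is statistically arbitrary,
  so causal attribution must come from the importance stage, not from the
  retained-variable list.
* Areas assume a spherical Earth and pre-aligned grids; no reprojection.
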