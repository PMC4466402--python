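# Methods

This note documents the models, the synthetic data they are validated
against, and the numerical and design choices a maintainer would want
explained. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spatial conventions

All layers live on a regular geographic grid (degrees, WGS84 assumed, no
reprojection): row 0 is the northernmost row, cells are square, and cell
membership is half-open — `[west, east) × (south, north]` — so every point
belongs to exactly one cell and points on the far east/south outer edge are
out of bounds. Values are double precision in whatever units the layers
carry; integer-coded temperature layers (°C × 10 style) are deliberately not
rescaled, because the environmental-filter widths are specified in raw layer
units. An `EnvStack` intersects the nodata masks of its layers at
construction, so a cell masked anywhere is masked everywhere. Occurrences on
masked cells or outside the grid are reported in a rejection list and
excluded — never silently dropped.

Raster I/O supports ESRI ASCII grids and single-band GeoTIFF. GeoTIFF goes
through `tifffile` with the standard georeferencing tags (ModelPixelScale,
ModelTiepoint, GDAL nodata); non-square cells and multi-band files are
rejected rather than guessed at.

## Environmental filtering

Raw presence archives are environmentally biased, so calibration records are
balanced in *environmental* space: the filter variables (default bio4,
bio16, bio17 with widths 200 each, in raw units) define hyper-rectangular
cells; exactly one record per occupied cell — picked uniformly at random
under the `FilterSpec` seed — goes to calibration, the rest to testing. The
calibration count equals the number of occupied cells and is therefore
seed-independent; only cell *membership* varies with the seed.

Cells are anchored at each variable's observed minimum (`cell k` covers
`[min + k·w, min + (k+1)·w)`): deterministic and scale-free, since no
canonical origin exists. One consequence is worth knowing: re-filtering the
calibration subset re-derives the anchor, and if the record that attained a
variable's minimum was not the one kept, the anchor shifts and two adjacent
cells can merge. `FilterResult` therefore records the anchors actually used,
and `FilterSpec.anchors` accepts them; with fixed anchors, filtering is
exactly idempotent on its own calibration output (tested).

Background and pseudo-absence draws are uniform over the unmasked extent,
with replacement, and are not forced to avoid presence cells. Pseudo-absence
counts are tied to testing-presence counts so that evaluation always runs at
prevalence 0.5.

## Bioclim envelope

Per variable, the tail percentile `p = min(F(x), 1 − F(x))` is computed from
the calibration empirical CDF and mapped to `min(2p, 1)`; the site score is
the minimum over variables, and any value outside the calibration min–max
scores 0. The CDF dialect (a documented choice, since several exist): with
`n` calibration values,

    F(x) = (#{v < x} + 0.5·(#{v = x} + 1)) / (n + 1).

This midrank-on-(n+1) convention makes the per-variable median of an
odd-sized calibration set score exactly 1 and gives the envelope a *soft
edge* — a point at the exact calibration minimum or maximum scores
`2/(n+1)`, not 0 — so calibration records never score zero under their own
model. Constant (degenerate) variables are flagged with a warning; the same
formula handles them (score 1 at the constant, 0 elsewhere).

## Maximum-entropy model

### Objective

The model is the Gibbs density over the landscape, `p(x) ∝ exp(β·f(x))`,
with features `f` = linear + quadratic per variable by default (pairwise
products optional, hinges not implemented — the workflow this package
supports deliberately restrains model complexity, and whole-variable
importances are what get reported). A binary predictor such as the host
layer enters linear-only, its square being itself.

The presence-scale penalized objective is

    −(1/m) Σ_presences log p(x_i) + Σ_j λ_j |β_j|,   λ_j = β_mult · s_j / √m,

with `s_j` the feature's sample SD over presences + background and `m` the
presence count. Features are standardized by their presences+background
mean/SD, so `s_j = 1` in fitting space. Fitting goes through the weighted
logistic contrast of presences (weight 1) against background (weight 100 per
point), whose slope estimates converge to the Gibbs coefficients as the
background weight grows; since that data term is `m` times the
presence-scale likelihood, the absolute penalty used in the logistic
objective is `m·λ_j = β_mult·√m` per standardized feature. With
`β_mult = 2` this penalty is deliberately strong: models stay sparse
(coefficients are exactly zero unless the presence/background contrast
exceeds roughly `β_mult/√m` standardized units), which is the point.

### Solver

Proximal Newton: an outer iteratively-reweighted-least-squares loop builds
the local weighted quadratic, an inner cyclic coordinate-descent loop with
soft-thresholding solves it exactly, and the step is backtracked along the
segment to the subproblem solution until the true penalized objective
decreases — making the recorded objective trace monotone (asserted in
tests). A plain majorize-minimize bound (0.25 curvature) is not used because
at the ~2.5·10⁻⁵ prevalence induced by the 1:100 weighting it underestimates
step sizes by orders of magnitude. Convergence: maximum coefficient change
< 1e-6 or objective change < 1e-9; iteration cap 500, with the objective
trace attached to the failure if it is ever hit. Degenerate (constant)
features are pinned at zero with a warning rather than rejected, because
synthetic configurations legitimately include inert decoy variables. The
solver is validated coefficient-by-coefficient (1e-4) against an independent
L-BFGS-B minimization of the identical objective via the positive/negative
coefficient split.

### Outputs

`raw` is the Gibbs density normalized over the fitting background (raw over
the background sums to 1, an asserted invariant). `logistic` is
`σ(η − avg_gain)` where `avg_gain = E_p[η]` under the fitted Gibbs
distribution — the classic sigmoid output at τ = 0.5, equal to 0.5
everywhere for a featureless model. Both are monotone in `η` and rank sites
identically; thresholding consumes the logistic output. Projection onto a
scenario does not clamp: extrapolating cells are counted and logged, not
altered. Models serialize to JSON (features, coefficients, normalizers, a
hash of the background matrix) and reload to bit-identical predictions.

## Evaluation and selection

* **AUC** is the rank-based (Mann–Whitney) statistic, ties counted ½,
  computed at prevalence 0.5 by construction (testing presences vs an equal
  number of pseudo-absences).
* **maxSSS threshold**: candidates are midpoints between consecutive
  distinct pooled scores plus ∓∞ sentinels; the rule is *suitable ⇔ score ≥
  threshold* everywhere in the package; ties among maxima break toward the
  lowest threshold (the more inclusive map).
* **Omission rate** is the fraction of testing presences below the
  threshold. In the pipeline, the threshold is computed from the testing
  presences and their pseudo-absences when a testing set exists, otherwise
  from calibration presences vs background.
* **AICc** uses `k` = number of exactly-nonzero coefficients and a log
  likelihood of landscape-standardized raw densities at the calibration
  occurrences — standardized over the current scenario's valid cells, not
  the background sample, so the value is auditable against the extent. AICc
  is undefined (None) when `n ≤ k + 1` or when an occurrence has zero
  density. Envelope models get no AICc (no likelihood is defined);
  cross-family comparison is by AUC only.
* **Permutation importance** permutes one variable jointly across presences
  + background, recomputes the training AUC, and reports mean drops over
  `n_reps` (default 10) permutations, floored at 0 and normalized to 100.
* **Variable contribution** is a declared surrogate for the reference
  implementation's training-path bookkeeping: each variable's summed
  |standardized coefficient| (product features split evenly), normalized to
  100. It is invariant to rescaling raw inputs (tested) and is *not*
  validated against any published percentages.

## Projection, stability, host coupling

Glacial predictions from the two circulation-model stand-ins are averaged
cell-wise *before* thresholding (order fixed by the workflow's definition).
Binary maps use integer codes 0/1 with −1 for nodata; stability maps code
never 0 / stable 1 / lost 2 / gained 3, and the four categories always
partition the valid cells (asserted).

The host predictor is the *thresholded* host map (its predicted presence,
not its continuous suitability), one layer per scenario; for hindcasts the
host's glacial layer is its glacial ensemble prediction binarized with the
host's current-data threshold, because the threshold is a property of the
fitted model, not of the scenario. Host–parasite overlap is normalized by
the parasite's range — the asymmetric question is whether the parasite can
find its host — and the reported change is `|overlap_present −
overlap_past| × 100` percentage points. The with/without-host comparison
fits both models on identical occurrences, identical background cells and
identical seeds, differing only by the host layer, and reports AICc for
both, relative likelihoods, paired evaluation reports, and the map of cells
suitable under climate-only but unsuitable once the host is included.

## Synthetic data: what it emulates, what it does not

Each climate layer is a linear spatial trend (distinct direction per
variable) plus moving-average-smoothed white noise — enough spatial
autocorrelation to make environmental filtering meaningful, trivially
reproducible, but *not* a geostatistical simulation. Default ranges follow
the raw-unit conventions of the standard bioclimatic layers over tropical
South America (seasonality spanning thousands of SD×100 units, quarter
precipitation spanning ~100–3000 mm), so the default filter widths of 200
raw units give realistic environmental-cell granularity. Glacial scenarios
are additive shifts (cooler, drier, more seasonal; two variants standing for
two circulation models); shifted precipitation can dip slightly below zero
at the landscape margin — the fields are abstract covariates, and clipping
would break the exact additive construction the tests verify. One smoothed
ocean mask is shared by all scenarios.

True niches are independent Gaussian responses per variable
(`suitability = max_suit · Π_v exp(−½((x_v − opt_v)/breadth_v)²)`), the
standard virtual-species device; occurrences sample cells with probability
proportional to suitability × optional bias, uniform position within the
cell, with replacement. Parasite sampling weights are climate suitability ×
host suitability^coupling, so `coupling_strength = 0` is exactly the
climate-only species (same seed ⇒ identical draws, tested).

Default study conditions mirror the real host–cleptoparasite analysis where
it states them: 290 host / 44 parasite raw occurrences, filter widths
(200, 200, 200) on bio4/bio16/bio17, β_mult = 2, 10,000 background points,
prevalence 0.5, two glacial scenarios averaged then thresholded. The default
host niche is broad (≈40 % of the landscape moderately suitable) and the
parasite niche narrow (≈8 %), active on bio4/bio16/bio17 with bio8/bio9 as
decoys for the parasite — the qualitative situation of a wide-ranged host
and a range-restricted parasite. Default coupling is 1 (the parasite truly
needs its host), which makes the with/without-host comparison informative;
the uncoupled regime is one config switch away.

What passing tests on these data do **not** show: real spatial sampling
bias (archive records cluster far more than suitability-proportional
sampling — the optional bias raster exists for that, and real raw archives
will retain a smaller calibration fraction than the synthetic default),
non-Gaussian niche shapes, interactions between climate axes, dispersal
limitation, or any fidelity of the glacial offsets to circulation-model
physics. Numeric agreement with any published AUC/importance percentages is
out of scope by design; the validation currency is parameter recovery on
known truth.

## Problem sizes and determinism

The test suite and acceptance script run entirely on synthetic data:
landscapes up to 100×100 cells, 200-presence fits with 10,000-point
backgrounds for the ten-seed recovery and host-coupling studies, 1,000 ×
2,000 for the null-data shrinkage property (a sample size at which the
asymptotic "uniform raw prediction" claim holds with margin, since the
activation threshold scales with the same √m as the sampling noise). All
randomness flows from explicit integer seeds through `numpy`'s Generator;
the full pipeline is bit-reproducible from its config (hashed and asserted).

## Known limitations

* The percent-contribution surrogate differs from the reference MaxEnt
  implementation's path-gain bookkeeping; only its invariances are tested.
* No hinge/threshold features, no clamping, no extrapolation flagging beyond
  a logged count; no mid-Holocene or future scenarios.
* The logistic-contrast fit approximates the Gibbs likelihood with finite
  (1:100) background weights; the approximation error is far below the L1
  shrinkage scale at the package's default sizes but is not zero.
* Min-anchored filtering is idempotent only up to anchor stability (see
  above); use recorded anchors for exact replay.
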