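# Methods

## Cellulose transfer model

The mechanistic core maps growing-season precipitation δ¹⁸O and relative
humidity to tree-ring cellulose δ¹⁸O:

    δ¹⁸O_TR = δ¹⁸O_P + ε_wc + (1 − f₀)(1 − h)(ε* + ε_k),   h = RH/100.

This is the standard Anderson-type simplification of the Craig–Gordon
leaf-water enrichment framework under two assumptions: atmospheric vapor in
isotopic equilibrium with source water (so the vapor term collapses into the
`(1 − h)` dryness scaling) and no explicit Péclet mixing or leaf-temperature
term — their aggregate damping is carried by `f₀`. Source water is taken to
be May–September precipitation directly; soil storage, snowmelt and
residence-time effects are deliberately out of scope, which means the model
is most defensible in humid regions and least in arid ones.

Parameters (all exposed on `CelluloseParams`):

| parameter | meaning | default | units |
|---|---|---|---|
| `f0` | damping/exchange factor: fraction of leaf-water enrichment exchanged back to source water during synthesis | 0.42 | – |
| `eps_eq` (ε*) | equilibrium liquid–vapor fractionation | 9 | ‰ |
| `eps_k` (ε_k) | kinetic fractionation during transpiration | 29 | ‰ |
| `eps_wc` | net biosynthetic water→cellulose offset | 27 | ‰ |

`f0`, ε* and ε_k defaults are the constants conventionally used with this
transfer function; ε_wc = 27‰ is the canonical cellulose–water biosynthetic
offset. All four are treated as spatially constant, which is a known
simplification — they vary among species and individuals.

The model is linear in δ¹⁸O_P with unit slope, strictly decreasing in RH
for `f₀ < 1`, and algebraically invertible; the inverse is used to
reconstruct δ¹⁸O_P rasters from predicted δ¹⁸O_TR and gridded RH. RH is
derived from temperature and vapor pressure via the Magnus form
`e_sat = 6.108·exp(17.27·T/(T + 237.3))` and `RH = 100·VAP/e_sat`. The
Magnus expression has no upper bound, so supersaturation artifacts in
gridded products (RH > 100%) are clamped to 100% and counted; clamped-then-
out-of-range inputs are domain errors. Humidity crosses the public API in
percent and is converted to fraction exactly once, inside the model.

Seasonal aggregation is an unweighted May–September mean (months 5–9
inclusive). The default is strict — any missing month inside the window
yields a missing value — because multi-year climatologies rarely have gaps
and silent partial means bias cross-site comparison; a lenient mode
averages the available months.

## Species standardization

Broadleaf cellulose is systematically depleted relative to conifers;
records are standardized by adding +1.9‰ to broadleaf values. The
operation is tracked by a flag (DataFrame column / record field) and
re-application is an error, since a double shift is a silent 3.8‰ bias.

## Isoscape estimator

`IsoscapeRegressor` is a scikit-learn `BaseEstimator`/`RegressorMixin`
wrapping either `xgboost.XGBRegressor` or
`sklearn.ensemble.RandomForestRegressor`. Both learners are first-class;
defaults are pinned for determinism and documentation rather than tuning:
500 trees for both, learning rate 0.05 and depth 4 for boosting
(`tree_method="hist"`, single thread), unlimited depth for the forest.
Cross-validation is a seeded shuffled 10-fold; the reported RMSE/R² are
pooled out-of-fold statistics, so the final refit on all data never
contaminates the metric (a memorization canary test asserts this).

Predictors are a table, not a hard-coded set: the helper
`build_feature_table` assembles longitude, latitude, elevation,
growing-season mean temperature and RH, a one-hot coarse climate class
(arid RH < 50%; else tropical T > 22 °C, boreal T < 8 °C, temperate
otherwise), and any caller-supplied named rasters. Prediction covers the
full 0.5° domain, including cells without nearby training sites.

Grid registration is cell centers with regular ascending axes; longitudes
in [−180, 180). Descending-latitude files are normalized on read.
Grid-to-site extraction is nearest-cell by default (bilinear optional);
sites outside the grid propagate missing values. Regridding is bilinear,
which preserves constant and coordinate-linear fields exactly.

## Driver attribution

Pearson correlations use pairwise-complete observations and the two-sided
t transform with n − 2 degrees of freedom. p-values are descriptive; no
multiple-testing correction is applied (matching common practice in spatial
proxy-network studies, and a known limitation).

Commonality analysis partitions the two-predictor R² via three ordinary
least-squares fits with intercept (`y~x1`, `y~x2`, `y~x1+x2`), computed
explicitly from residual and total sums of squares so the fitting method is
pinned rather than delegated:

    unique₁ = R²₁₂ − R²₂,  unique₂ = R²₁₂ − R²₁,
    common = R²₁ + R²₂ − R²₁₂,  total = R²₁₂.

Unique components are non-negative by construction (tiny negative round-off
is clipped and re-absorbed into the joint term so the additive identity
holds to machine precision); the joint component can be legitimately
negative (suppression). Near-collinear predictors (|r| > 0.999) produce a
warning, not an error. Tables report 2-decimal percentages; internal values
stay full precision.

## Regions and elevation gradients

Default subregions are editable bounding boxes: ISM 5–33°N/70–100°E, EASM
20–45°N/100–125°E, arid westerlies 35–50°N/55–95°E, high latitudes >50°N.
A GeoJSON FeatureCollection with faithful polygon outlines can replace them;
overlap (positive-area intersection) is a configuration error at load time.
Polygon edges are inclusive; a point on a shared edge of two adjacent
regions is assigned to the first region in configuration order. Sites
outside all regions are labeled `unassigned` and retained for
continental-scale analysis.

The isotope–elevation gradient is the OLS slope of δ¹⁸O_TR on elevation in
meters, reported ×100 (‰ per 100 m), with the Pearson r/p of the same
relationship. Site-table elevation is authoritative; a DEM lookup is a
deliberate non-feature. Monsoon-boundary detection from the isoscape is
descriptive in the literature and has no agreed algorithm, so it is not
implemented.

## Synthetic generator

The generator emulates the statistical structure of the continental Asian
setting so every downstream stage is testable offline. Defaults are the
study conditions: a 0.5° grid over 60–140°E / 5–70°N, 313 tree-ring sites,
252 precipitation-isotope stations, ~30% broadleaf sites, and site
allocation across regimes of ISM/EASM/arid/high-lat ≈ 0.42/0.33/0.16/0.09
(mirroring regional n of roughly 130/102/52/29).

- **Terrain**: gentle latitudinal base plus a plateau bump (4200 m, centred
  31°N/88°E) and a monsoon-flank arc ridge (3200 m, centred 27°N/85°E),
  giving the monsoon band the heavy right tail of elevations that the
  gradient analysis needs, plus smoothed noise.
- **Climate**: temperature with a latitudinal gradient, continental
  seasonal cycle and 6.5 K/km terrain lapse; an RH climatology that is
  humid and deliberately *flat* across the monsoon south (so humidity
  carries no systematic elevation signal inside the ISM box), dry in the
  arid interior, moderately humid at high latitudes. Vapor pressure is
  constructed so the Magnus-based RH recovers the target field exactly.
- **δ¹⁸O_P**: piecewise-constant latitude-band means, default
  (−6, −3.5, −8)‰ for <30°N / 30–50°N / >50°N — the sandwich by
  construction — with sharp transitions, because the zero-noise contract
  (monsoon-subdomain elevation regression recovers the configured lapse
  exactly) requires a constant latitudinal base inside the lapse subdomain.
  The −0.15‰/100 m lapse applies below 30°N within 70–100°E. The seasonal
  harmonic is centred so its May–September mean is exactly zero, making
  May–September means equal the base field by construction.
- **Observations**: site δ¹⁸O_TR = forward model at the nearest grid cell
  − 1.9‰ for broadleaf sites + N(0, 1‰); stations report the cell's
  monthly series + N(0, 0.5‰) per month. Generating truths are retained in
  `*_true` columns. Band means and noise levels were fixed once so that
  simulated observations span realistic envelopes (sites within 15–38‰,
  station May–September means within −20 to +3‰).

Randomness flows from one integer seed through per-stage
`numpy.random.SeedSequence` children, so identical configurations are
bit-for-bit reproducible and stages can be regenerated independently.

What the generator does **not** emulate: GCM moisture-transport physics,
interannual variability (records are climatological means), spatial
autocorrelation of observation noise (config option, off by default), and
amount-effect coupling between precipitation amount and isotopes. Passing
recovery tests therefore demonstrates that the estimators recover the
assumed structure at realistic noise levels — not that real Asian data obey
that structure.

## Numerical choices and degenerate inputs

- Forward/inverse round trip is exact algebra; tested to 1e−10 over the
  full parameter envelope.
- Temperatures at or below the Magnus singularity (−237.3 °C) or outside
  (−90, 60) °C are domain errors; negative vapor pressures likewise.
- Zero-variance inputs: correlation and commonality raise domain errors; a
  constant isotope response in the elevation fit returns slope 0, r 0
  rather than erroring, since that input is well-posed.
- NetCDF I/O uses the classic format via the SciPy backend with float64
  variables, so write-then-read round trips are bit-exact.
- Pipeline artifacts embed a SHA-256 hash of the analysis configuration
  (excluding the output path) for provenance; identical configurations
  yield byte-identical tables.

## Problem sizes used in the shipped analyses

Unit and recovery tests run the generator at the default continental scale
(313 sites, 160×130 grid) for up to 100 seeds per property, with 10-seed
variants for the quick structural checks; the acceptance script runs one
full seeded pipeline (both learners, 10-fold CV, full-domain prediction).
These sizes match the study conditions the generator encodes rather than
being scaled-down surrogates.

## Known limitations

- The transfer model omits soil-water processes, explicit vapor isotopes,
  leaf temperature and Péclet mixing; constants are spatially uniform.
- Cross-validation is random K-fold, not spatially blocked; with spatially
  autocorrelated fields it is an optimistic estimate of extrapolation
  skill. No uncertainty quantification beyond CV metrics.
- Commonality analysis is limited to the two-predictor case by design.
- Default region geometries are bounding boxes, not the faithful
  circulation-regime outlines; supply a region file for serious regional
  work.
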