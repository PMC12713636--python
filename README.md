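# trisoscape

Continental-scale isoscapes of tree-ring cellulose oxygen isotopes
(δ¹⁸O_TR), for isotope ecologists and dendroclimatologists who want to go
from a compilation of multi-year site means to (i) a gridded δ¹⁸O_TR
prediction surface, (ii) an attribution of its spatial variance to
precipitation isotopes versus atmospheric humidity, and (iii) regional
isotope–elevation lapse rates — with a fully seeded synthetic generator of
Asian-style networks so the whole pipeline is testable without any data
downloads.

## The science in brief

Cellulose δ¹⁸O records the isotopic composition of source water (taken as
growing-season precipitation, δ¹⁸O_P) plus an evaporative leaf-water
enrichment controlled by relative humidity. The package implements the
standard Anderson-type simplification of the Craig–Gordon framework:

    δ¹⁸O_TR = δ¹⁸O_P + ε_wc + (1 − f₀)(1 − h)(ε* + ε_k)

where `h = RH/100`, `f₀ = 0.42` is the damping/exchange factor, `ε* = 9‰`
the equilibrium liquid–vapor fractionation, `ε_k = 29‰` the kinetic
fractionation, and `ε_wc = 27‰` the biosynthetic water→cellulose offset.
The model is linear in δ¹⁸O_P and algebraically invertible, so gridded
δ¹⁸O_TR plus RH yields a reconstructed δ¹⁸O_P surface. Relative humidity
is computed from temperature and vapor pressure with the Magnus saturation
vapor-pressure formula `e_sat = 6.108·exp(17.27·T/(T+237.3))` (hPa, °C).

Around that core:

- **Isoscape generation** — gradient-boosted trees (XGBoost) and random
  forest regressors predict δ¹⁸O_TR on a 0.5°×0.5° lattice from longitude,
  latitude, elevation, growing-season climate and a coarse climate class,
  with seeded 10-fold cross-validation (scikit-learn estimator API).
- **Driver attribution** — Pearson correlations and two-predictor
  commonality analysis, which splits the R² of `δ¹⁸O_TR ~ RH + δ¹⁸O_P`
  into unique RH, unique δ¹⁸O_P and a joint component (possibly negative).
- **Regional analysis** — point-in-polygon assignment to four circulation
  regimes (Indian Summer Monsoon, East Asian Summer Monsoon, arid
  westerlies, high latitudes) and OLS isotope–elevation gradients reported
  in ‰ per 100 m.
- **Synthetic networks** — a deterministic generator producing the
  latitudinal "sandwich" δ¹⁸O_P structure (enriched 30–50°N, depleted
  poleward and equatorward), a Tibetan-Plateau-like terrain, a −0.15‰/100 m
  monsoon-region lapse, and site/station observations built through the
  forward model plus noise, with generating truths retained for recovery
  tests.

## Worked example

```python
from trisoscape import *

cfg = SyntheticConfig(seed=7)
grid = gen_d18op_field(cfg, gen_climate_grid(cfg))
sites = assign_region(standardize_species(gen_sites(cfg, grid)))

feats = build_feature_table(sites, grid)
iso = predict_isoscape(fit_isoscape(sites, feats, learner="xgboost", seed=7), grid)
print(f"XGBoost isoscape: 10-fold CV RMSE = {iso.cv_rmse:.2f} permil, R2 = {iso.cv_r2:.2f}")

y = sites["d18o_tr_std"]
rh = extract_at_sites(grid.seasonal_mean("rh"), sites)
p  = extract_at_sites(grid.seasonal_mean("d18op"), sites)
print(f"r(d18O_TR, d18O_P) = {pearson(p, y).r:+.2f}   r(d18O_TR, RH) = {pearson(rh, y).r:+.2f}")

c = commonality_two(y, rh, p)
print(f"commonality: unique RH {c.unique_rh:.2f}%  unique d18O_P {c.unique_p:.2f}%  "
      f"joint {c.common:.2f}%  total {c.total:.2f}%")

ism = sites[sites["region"] == "ISM"]
f = elevation_gradient(ism)
print(f"ISM lapse rate: {f.slope_per_100m:+.2f} permil/100 m (r = {f.r:+.2f}, n = {f.n})")
```

prints

```
XGBoost isoscape: 10-fold CV RMSE = 1.34 permil, R2 = 0.88
r(d18O_TR, d18O_P) = +0.85   r(d18O_TR, RH) = -0.87
commonality: unique RH 21.36%  unique d18O_P 17.27%  joint 54.40%  total 93.02%
ISM lapse rate: -0.16 permil/100 m (r = -0.77, n = 132)
```

Reading the numbers: the fitted isoscape explains ~88% of held-out spatial
variance at a residual of ~1.3‰ (the generator's site noise is 1‰).
δ¹⁸O_TR correlates positively with precipitation isotopes and negatively
with humidity — drier air enriches leaf water and hence cellulose. The
commonality partition shows a large joint component because the synthetic
climate couples the two drivers spatially (dry mid-latitudes are also
isotopically enriched). Inside the monsoon region, cellulose δ¹⁸O thins
with altitude at close to the generating −0.15‰/100 m lapse.

The same pipeline runs from the shell (`trisoscape simulate | isoscape |
reconstruct | drivers | elevation | run-all`); real site CSVs and NetCDF
climate/isotope rasters drop in wherever synthetic ones are used (see
`trisoscape run-all --config config.yaml`).

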