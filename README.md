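# latrange

Latitudinal range-size analysis for bounded biogeographic domains:
Rapoport's-rule estimators, a Monte Carlo mid-domain-effect null model,
equal-area mean-range-size mapping, and environmental
correlation/regression stages — with a synthetic-data generator so the
whole pipeline is testable end to end without any external data.

## The scientific problem

Rapoport's rule predicts that species occupy broader latitudinal ranges
at higher latitudes. Whether a fauna supports the rule depends heavily
on how the band statistics are computed, and an apparent gradient can be
produced by geometry alone: when ranges must fit inside a bounded
domain, random placement concentrates large ranges near the centre (the
mid-domain effect, MDE). This package implements the standard toolkit
for separating those signals for a one-dimensional (latitudinal) study
domain such as a country's latitudinal span:

- **Four estimators of the range-size/latitude relationship.** For a
  species with range terminals $l_{\min}, l_{\max}$, its extent is
  $R = l_{\max} - l_{\min}$ and its mid-point $m = (l_{\min}+l_{\max})/2$.
  With the domain cut into 5° bands, Stevens' method averages $R$ over
  all species overlapping each band; the mid-point method assigns each
  species to the band holding $m$; Pagel's method assigns by $l_{\max}$;
  the cross-species method regresses $R$ on $m$ with no binning. Band
  profiles are fitted with linear and second-order polynomial OLS, the
  better model chosen by adjusted $R^2$, and a verdict issued
  (supported / hump-shaped / not supported).
- **The MDE null model.** Empirical extents are kept (each used exactly
  once per replicate) and re-placed with mid-points drawn uniformly on
  the feasible interval $[l_{lo}+R/2,\; l_{hi}-R/2]$; 10 000 Monte Carlo
  replicates give per-band expected mean extents with Monte Carlo
  errors, a quadratic null curve, and a linear regression of the
  empirical profile on the null whose $R^2$ measures the MDE's
  explanatory power.
- **Equal-area mapping.** Ranges are rasterized onto 100 km × 100 km
  cells in an Albers equal-area projection (cells with < 50 % land are
  excluded as coastal) and per-cell mean extent is mapped.
- **Environmental stages.** Pearson correlations of nine predictors
  (AMT, AP, TAR, TS, PS, NDVI, PET, ALT, ALR) with mean range size and
  latitude, a |r| > 0.7 collinearity screen, and per-group bidirectional
  stepwise Gaussian GLMs.

The synthetic generator emulates a 515-species terrestrial mammal
assemblage on an 18–54° N domain: truncated log-normal extents
moment-matched to mean 11.01° / SD 8.13°, an optional extent–mid-point
coupling ("Rapoport strength"), a ragged synthetic coastline, and
environmental layers with the latitude-correlation signs typical of an
East-Asian monsoon domain.

## Worked example

```python
import numpy as np
from latrange import *
from latrange.synth import RangeGenConfig, generate_ranges

domain = Domain(18, 54)
bands = make_band_system(domain, 5.0)          # eight bands, 15–20 … 50–55
ranges = generate_ranges(RangeGenConfig.china_mammals(seed=1))

summ = summarize_extents(ranges)
print(f"n = {summ.raw.n}, extent mean = {summ.raw.mean:.2f}, "
      f"SD = {summ.raw.sd:.2f}, median = {summ.raw.median:.2f}, "
      f"skewness = {summ.raw.skewness:.2f}")

prof = midpoint_profile(ranges, bands)
cfg = NullModelConfig(domain=domain, bands=bands, n_reps=10_000, seed=1)
null = simulate_null([r.lat_max - r.lat_min for r in ranges], cfg)
curve = fit_null_curve(null)
print("null band means:", np.round(null.null_mean, 2))
print(f"null curve: y = {curve.intercept:.3f} + {curve.slope:.3f} x "
      f"{curve.quad:+.4f} x^2  (R2 = {curve.r2:.3f})")
reg = regress_empirical_on_null(prof, null)
print(f"MDE regression: beta = {reg.beta:.3f}, R2 = {reg.r2:.3f}")
```

prints

```
n = 515, extent mean = 10.68, SD = 7.99, median = 8.16, skewness = 1.12
null band means: [ 2.05  5.36  8.9  12.78 15.22 10.14  6.75  3.57]
null curve: y = -31.826 + 2.485 x -0.0347 x^2  (R2 = 0.901)
MDE regression: beta = 1.056, R2 = 0.980
```

The generated extents reproduce the target moments (right-skewed, mean
≈ 11°, SD ≈ 8°). The null profile is hump-shaped — the fitted quadratic
coefficient is negative, with expected mean ranges peaking in the
mid-latitudes — and because this synthetic assemblage is placed by
geometry alone, the null model explains nearly all of the band-level
variation in mean range size (R² = 0.98): the textbook mid-domain
signature.

A command-line interface covers the same pipeline
(`latrange synth | bands | mde | map | env | verify`); every command
writes a manifest with content digests for reproducibility.

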