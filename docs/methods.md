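# Methods

This note documents the statistical model behind `latrange`, the
choices made where the standard methods leave details open, and what
the synthetic data do and do not establish about real assemblages.

## Band systems and the four estimators

The study domain is a closed latitudinal interval (default 18–54° N).
Bands are half-open intervals $[lo, hi)$ of fixed width (default 5°)
anchored at the largest multiple of the band width not above the
domain's southern edge; for 18–54° N this gives the conventional eight
bands 15–20 … 50–55. The half-open convention makes boundary
assignment unambiguous; the single exception is the domain's top
latitude, which closes into the topmost band so every latitude in the
domain belongs to exactly one band.

The four estimators answer subtly different questions and are all
reported:

- **Stevens**: a species contributes its extent to every band its
  interval overlaps with positive measure (a zero-extent species to the
  band containing its point). Band samples are not independent — a
  wide-ranging species appears in many bands — so per-band counts sum
  to ≥ n and the profile is strongly autocorrelated.
- **Mid-point** and **Pagel**: each species counted once, in the band
  holding its mid-point or its northern terminus respectively; counts
  partition the species set.
- **Cross-species**: the unbinned per-species (mid-point, extent)
  scatter.

Empty bands carry NaN means, never zero; trend fits drop them pairwise.

### Trend fitting and model selection

Band profiles (and the cross-species scatter) are fitted by OLS with a
linear and a second-order polynomial form. Raw $R^2$ cannot prefer the
linear model over its nested quadratic, so selection uses adjusted
$R^2$; raw $R^2$ is reported on every candidate. Band-level
regressions are unweighted (per-band n is reported so weighted variants
remain possible). The verdict rule: Rapoport's rule is *supported* when
the selected form is linear with a significantly positive slope
(α = 0.05, configurable); a selected quadratic with negative curvature
and an interior maximum is *hump-shaped*; anything else is *not
supported*.

## The mid-domain null model

The null model keeps the empirical extent multiset — every extent used
exactly once per replicate, i.e. sampling without replacement — and
re-places each range by drawing its mid-point uniformly on the feasible
interval where the range fits inside the domain. Because placement
depends only on a range's extent, permuting the extents before
placement does not change the distribution of any band statistic; the
simulation therefore places the extent vector directly, while
`reshuffle_once` retains the permutation for identity-tracking uses.

Per replicate the mid-point-method band profile is computed. Per band,
replicate means are averaged **conditionally on the band being
non-empty**, with the empty-rate reported separately; an unconditional
average would require an arbitrary value for empty bands. The Monte
Carlo standard error is the SD of per-replicate band means divided by
√(non-empty replicates), and 2.5 %/97.5 % empirical quantiles are
reported. The default is 10 000 replicates; for 515 species this runs
in about a second (the replicate loop is vectorised and chunked to
bound memory).

The null band means are summarised by a quadratic OLS curve on band
centres (band centres rather than edges; with 5° bands the choice
shifts the fitted peak by 2.5° and nothing else). The MDE's
explanatory power is the $R^2$ of an OLS regression of empirical band
means on null band means over the shared non-missing bands.
Normality (one-sample Kolmogorov–Smirnov against a moment-matched
normal) and homoscedasticity (Levene) diagnostics are computed for
regression inputs; degenerate zero-variance inputs are flagged and the
tests skipped rather than reported as meaningless numbers.

## Equal-area gridding

The analysis grid is built in an Albers equal-area conic projection
(spherical formulas, radius 6371.0072 km; default standard parallels
25°/47° N, origin 36° N 104° E — suited to a China-extent domain and
fully configurable). Cells are 100 km squares in projected space, so
all have identical area. Cell membership uses the centroid rule
throughout: a species occupies a cell when its range geometry covers
the cell centroid's geographic coordinates, and a fine-resolution pixel
contributes to the cell containing its centre. The centroid rule is
order-independent and matches common macroecological practice; an
area-overlap rule would change only boundary cells.

Land fraction is the fraction of fine landmask pixels inside a cell
that are land; cells with land fraction strictly below 0.5 are excluded
as coastal (0.50 exactly is retained). Per unmasked cell the range-size
map is the arithmetic mean of the latitudinal extents of occupying
species; empty cells are flagged, not zeroed. Environmental layers are
aggregated per cell by the mean, except altitude range (ALR), which is
the within-cell max − min of fine-resolution altitude — a heterogeneity
measure — while ALT is the within-cell mean. Rasters are exchanged as
ESRI ASCII grids (plain text, south-up in memory, north-up on disk per
the format convention).

## Environmental stages

Rows of the analysis table are unmasked cells with a defined mean
extent and complete environmental values; the retained row count is
logged and sets the regression degrees of freedom. Pearson
correlations of each predictor with mean extent ($r_m$) and with
centroid latitude ($r_l$) are two-sided; constant columns yield
undefined correlations rather than errors. Pairs with |r| > 0.7 are
flagged as collinear for information only — selection handles the
redundancy.

The per-group models are Gaussian GLMs with identity link (ordinary
linear models; the reported statistics are t values and adjusted $R^2$)
fitted by bidirectional stepwise selection with p-to-enter 0.05 and
p-to-remove 0.10. The partial F for adding one variable equals the
square of its t statistic, so entry tests use coefficient p-values. By
default the entry threshold is Šidák-adjusted for the number of
candidates screened at that step, $1-(1-p_{enter})^{1/k}$, making
`p_enter` the family-wise probability of admitting any variable when
the response is pure noise (with three candidates the uncorrected rule
admits a spurious variable ~14 % of the time); the classic uncorrected
rule is available via `protected_entry=False`. Variable groups:
mean climate (AMT, AP), climate variability (TAR, TS, PS), ambient
energy (NDVI, PET), topography (ALT, ALR).

Spatial autocorrelation among cells is **not** corrected; every report
carries a note that significance tests treat cells as independent and
are therefore anti-conservative.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume,
not real biogeography:

- **Extents**: log-normal truncated to (0, domain width], with the
  underlying (μ, σ) solved by moment matching so the truncated
  distribution has a requested mean and SD. The China-mammal reference
  configuration (`RangeGenConfig.china_mammals`) targets
  n = 515 species with mean 11.01° and SD 8.13° on an 18–54° N domain,
  giving the right-skewed raw distribution and approximately
  left-skewed log10 transform characteristic of real range-size data.
- **Placement**: with zero coupling, mid-points are uniform on each
  extent's feasible interval — the same construction as the null model,
  so the only structure in the band profiles is the geometric
  constraint. The reference configuration uses zero coupling: it is a pure mid-domain
  world. With positive `rapoport_strength` s, a latent position t is
  drawn uniformly on the domain and the extent's log-location is
  shifted by s·(t/W − ½) before the range is clipped to the domain;
  expected extent then increases monotonically northward. The recovery
  studies use s = 2.0 — about a sevenfold south-to-north increase in
  median extent, comparable to the strongest published band gradients —
  an effect size at which band-level regressions on eight points have
  adequate power at n = 500 species.
- **Landmask**: all-land, half-plane (straight coast on a cell
  boundary), or a ragged seeded coast (smoothed random walk) producing
  cells across the full land-fraction spectrum including some below
  0.5.
- **Environmental layers**: per-cell linear trends in centroid latitude
  plus Gaussian noise. Trend signs follow the latitude-correlation
  structure of an East-Asian monsoon domain (temperature, precipitation,
  NDVI, PET and elevation decline northward; continentality/seasonality
  measures increase). With zero noise $r_l = ±1$ exactly; magnitudes
  and noise SDs are plausible for the variables' units but are not
  calibrated to any real layer.

Every generator is deterministic given its seed, and every output can
carry a manifest (seed, config digest).

**What passing tests show — and don't.** The synthetic assemblage has
independent species, one-dimensional box ranges, linear environmental
trends and isotropic noise. Tests against it establish that the
estimators, the null model and the selection machinery are implemented
correctly and have the expected statistical behaviour under known
truth. They say nothing about taxonomic error, spatially coherent range
shapes, non-linear climate surfaces, or spatial autocorrelation in real
data — the last of which is deliberately left uncorrected, as noted
above.

## Numerical choices and degenerate inputs

- Sample SD uses the n−1 denominator; skewness is the adjusted
  Fisher–Pearson statistic, reported as NaN for n < 3 or zero variance.
- Zero-extent species are retained everywhere except log10 summaries,
  where they are excluded and counted.
- A full-domain extent has a degenerate feasible interval; its
  mid-point is the domain centre.
- An extent exceeding the domain width is a validation error naming the
  species.
- Degenerate regression designs (constant predictor, too few points)
  raise a fitting error rather than returning NaN coefficients.
- Monte Carlo checks in the test suite use 3×(MC standard error) bands,
  with a 1e-9 absolute floor where a quantity is deterministic up to
  round-off.

## Problem sizes

Default analysis sizes — 515 species, 10 000 null replicates, a
~68 × 45-cell grid (≈ 3 000 cells, ≈ 2 000 with data), 100-seed
recovery studies at n = 500 species or 900 cells — were chosen so each
stage's sampling error is small relative to the effects under study;
the full pipeline completes in seconds on one core.
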