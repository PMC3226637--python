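"""Synthetic data with the statistical structure the analyses assume.

Stands in for an undeposited species range database and un-downloadable
climate layers: species latitudinal ranges with a right-skewed extent
distribution (truncated log-normal, moment-matched to configurable
mean/SD targets), optional extent–midpoint coupling (a tunable
"Rapoport strength"), equal-area occupancy rasters, a ragged synthetic
landmask, and nine environmental layers whose latitudinal trends carry
configurable signs. Every generator is deterministic given its seed.

The China-mammal reference configuration emulates a 515-species
terrestrial mammal assemblage on an 18–54° N domain with extent mean ≈ 11.01° and
SD ≈ 8.13°, placed by geometry alone (no extent–midpoint coupling), so
the mid-domain effect is the only structure in the band profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats as sps

from latrange.grid import (
    AlbersEqualArea,
    EqualAreaGrid,
    FineField,
    OccupancyRaster,
    projected_extent,
)
from latrange.ranges import ConfigurationError, Domain, SpeciesRange

CHINA_BBOX = (18.0, 54.0, 73.0, 135.0)  # lat_min, lat_max, lon_min, lon_max


def truncated_lognormal_params(
    mean: float, sd: float, upper: float
) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal such that a log-normal
    truncated to (0, upper] has the requested mean and SD.

    Solved by moment matching; the truncated moments are
    E[X^k | X<=U] = exp(k*mu + k^2 s^2/2) * Phi((lnU-mu-k s^2)/s) / Phi((lnU-mu)/s).
    """
    if not (0 < mean < upper):
        raise ConfigurationError(f"target mean {mean} must lie in (0, {upper})")
    lnU = math.log(upper)

    def moments(params):
        mu, ls = params
        s = math.exp(ls)
        z = (lnU - mu) / s
        denom = sps.norm.cdf(z)
        m1 = math.exp(mu + s**2 / 2) * sps.norm.cdf(z - s) / denom
        m2 = math.exp(2 * mu + 2 * s**2) * sps.norm.cdf(z - 2 * s) / denom
        return m1, m2

    target_m2 = sd**2 + mean**2
    cv2 = (sd / mean) ** 2
    s0 = math.sqrt(math.log1p(cv2))
    x0 = np.array([math.log(mean) - s0**2 / 2, math.log(s0)])

    def resid(params):
        m1, m2 = moments(params)
        return [m1 - mean, m2 - target_m2]

    sol = optimize.root(resid, x0, method="hybr")
    if not sol.success:
        raise ConfigurationError(
            f"moment matching failed for mean={mean}, sd={sd}, upper={upper}"
        )
    mu, ls = sol.x
    return float(mu), float(math.exp(ls))


@dataclass(frozen=True)
class RangeGenConfig:
    """Configuration of the species-range generator.

    ``rapoport_strength`` couples extent to midpoint: 0 places a
    truncated log-normal extent sample by uniform feasible midpoints
    (extent and position share only the geometric constraint); positive
    values shift the log-scale location of the extent distribution
    linearly from south (−strength/2) to north (+strength/2).
    """

    n_species: int = 515
    domain: Domain = field(default_factory=lambda: Domain(18.0, 54.0))
    mean_extent: float = 11.01
    sd_extent: float = 8.13
    rapoport_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if not (0 < self.mean_extent < self.domain.width):
            raise ConfigurationError(
                f"mean extent {self.mean_extent} infeasible for domain width "
                f"{self.domain.width}"
            )

    @classmethod
    def china_mammals(cls, seed: int = 0) -> "RangeGenConfig":
        """The 515-species China-mammal-like configuration."""
        return cls(seed=seed)


def _sample_truncated_lognormal(
    mu: float, sigma: float, upper: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    zmax = (math.log(upper) - mu) / sigma
    u = rng.random(n) * sps.norm.cdf(zmax)
    return np.exp(mu + sigma * sps.norm.ppf(u))


def generate_ranges(config: RangeGenConfig) -> list[SpeciesRange]:
    """Draw a synthetic species-range sample.

    With zero coupling, extents come from the moment-matched truncated
    log-normal and midpoints are uniform on each extent's feasible
    interval. With positive coupling, a latent position is drawn
    uniformly on the domain, the extent's log-location is shifted with
    that position, and the resulting range is clipped to the domain (so
    realized extents near the boundaries can shrink). Reproducible from
    ``config.seed``.
    """
    d = config.domain
    W = d.width
    rng = np.random.default_rng(config.seed)
    mu, sigma = truncated_lognormal_params(config.mean_extent, config.sd_extent, W)
    n = config.n_species
    ids = [f"sp{i:04d}" for i in range(n)]

    if config.rapoport_strength == 0:
        extents = _sample_truncated_lognormal(mu, sigma, W, n, rng)
        lo = d.lat_lo + extents / 2.0
        mid = lo + rng.random(n) * (W - extents)
        lat_min, lat_max = mid - extents / 2.0, mid + extents / 2.0
    else:
        mid = d.lat_lo + rng.random(n) * W
        z = (mid - d.lat_lo) / W - 0.5
        shift = config.rapoport_strength * z
        zmax = (np.log(W) - (mu + shift)) / sigma
        u = rng.random(n) * sps.norm.cdf(zmax)
        extents = np.exp(mu + shift + sigma * sps.norm.ppf(u))
        lat_min = np.maximum(d.lat_lo, mid - extents / 2.0)
        lat_max = np.minimum(d.lat_hi, mid + extents / 2.0)
    return [
        SpeciesRange(i, float(a), float(b)) for i, a, b in zip(ids, lat_min, lat_max)
    ]


# ---------------------------------------------------------------------------
# Landmask


def generate_landmask(
    bbox: tuple[float, float, float, float] = CHINA_BBOX,
    projection: AlbersEqualArea | None = None,
    cell_size: float = 100.0,
    pixel_size: float = 10.0,
    model: str = "ragged",
    coast_fraction: float = 0.85,
    amplitude: float | None = None,
    seed: int = 0,
) -> FineField:
    """Fine-resolution boolean landmask over the grid extent of ``bbox``.

    Models: ``all_land`` (no water); ``half_plane`` (a straight
    north–south coast at ``coast_fraction`` of the grid width, aligned to
    a cell boundary so boundary cells are exactly land or water);
    ``ragged`` (a seeded, smoothed meandering coast producing cells
    across the whole land-fraction spectrum, including some below 0.5).
    """
    if projection is None:
        projection = AlbersEqualArea()
    x0, y0, nx, ny = projected_extent(bbox, projection, cell_size)
    fnx = int(round(nx * cell_size / pixel_size))
    fny = int(round(ny * cell_size / pixel_size))
    xs = x0 + (np.arange(fnx) + 0.5) * pixel_size
    ys = y0 + (np.arange(fny) + 0.5) * pixel_size

    if model == "all_land":
        mask = np.ones((fny, fnx), dtype=bool)
    elif model == "half_plane":
        coast_x = x0 + cell_size * round(coast_fraction * nx)
        mask = np.broadcast_to(xs < coast_x, (fny, fnx)).copy()
    elif model == "ragged":
        rng = np.random.default_rng(seed)
        amp = cell_size if amplitude is None else amplitude
        # smoothed random walk along y gives a meandering east coast
        steps = rng.standard_normal(fny)
        walk = np.cumsum(steps)
        kernel = np.ones(25) / 25.0
        smooth = np.convolve(walk, kernel, mode="same")
        smooth = (smooth - smooth.mean()) / (np.std(smooth) + 1e-12)
        coast_x = x0 + coast_fraction * nx * cell_size + amp * smooth
        mask = xs[None, :] < coast_x[:, None]
    else:
        raise ConfigurationError(f"unknown coastline model {model!r}")
    return FineField(values=mask.astype(float), x0=x0, y0=y0, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Occupancy


def generate_occupancy(
    ranges: list[SpeciesRange],
    grid: EqualAreaGrid,
    lon_span: tuple[float, float] = (10.0, 50.0),
    lon_bounds: tuple[float, float] = (CHINA_BBOX[2], CHINA_BBOX[3]),
    seed: int = 0,
) -> tuple[list[OccupancyRaster], list[str]]:
    """Occupancy rasters from latitudinal ranges plus generated
    longitudinal spans.

    Each species occupies the unmasked cells whose centroid latitude
    lies within its latitudinal range (bounds inclusive) and whose
    centroid longitude lies within a span of width drawn uniformly from
    ``lon_span``, positioned uniformly inside ``lon_bounds``. Returns
    the rasters and the ids of species that hit no unmasked cell.
    """
    rng = np.random.default_rng(seed)
    lon, lat = grid.centroids_geographic()
    unmasked = ~grid.mask
    rasters, unplaced = [], []
    lo_b, hi_b = lon_bounds
    for r in ranges:
        w = rng.uniform(*lon_span)
        w = min(w, hi_b - lo_b)
        west = lo_b + rng.random() * (hi_b - lo_b - w)
        occ = (
            (lat >= r.lat_min) & (lat <= r.lat_max)
            & (lon >= west) & (lon <= west + w)
            & unmasked
        )
        cells = frozenset(zip(*map(lambda a: a.tolist(), np.nonzero(occ))))
        rasters.append(OccupancyRaster(r.species_id, cells))
        if not cells:
            unplaced.append(r.species_id)
    return rasters, unplaced


# ---------------------------------------------------------------------------
# Environmental layers


@dataclass(frozen=True)
class EnvVarSpec:
    """Latitudinal trend specification for one environmental layer."""

    intercept: float  # value at the domain's southern edge
    slope: float  # units per degree latitude; sign fixes the r_l sign
    noise_sd: float


# Trend signs follow the latitude-correlation structure typical of an
# East-Asian monsoon domain: temperature, precipitation, vegetation
# greenness, evapotranspiration and elevation all decline northward
# while continentality/seasonality measures increase.
CHINA_MONSOON_ENV: dict[str, EnvVarSpec] = {
    "AMT": EnvVarSpec(24.0, -0.70, 2.0),  # °C
    "AP": EnvVarSpec(1900.0, -42.0, 260.0),  # mm
    "TAR": EnvVarSpec(12.0, 0.85, 1.6),  # °C
    "TS": EnvVarSpec(4.0, 0.30, 0.6),  # °C (SD×100 scale conventions vary)
    "PS": EnvVarSpec(35.0, 1.1, 9.0),  # mm
    "NDVI": EnvVarSpec(0.70, -0.004, 0.12),  # unitless
    "PET": EnvVarSpec(1500.0, -14.0, 110.0),  # mm
    "ALT": EnvVarSpec(2400.0, -30.0, 700.0),  # m
    "ALR": EnvVarSpec(1300.0, -18.0, 420.0),  # m
}


@dataclass(frozen=True)
class EnvGenConfig:
    """Configuration of the environmental-layer generator."""

    variables: dict[str, EnvVarSpec] = field(
        default_factory=lambda: dict(CHINA_MONSOON_ENV)
    )
    lat_ref: float = CHINA_BBOX[0]  # latitude at which intercepts apply
    noise_scale: float = 1.0  # multiplies every noise SD
    seed: int = 0

    def with_noise_scale(self, scale: float) -> "EnvGenConfig":
        return replace(self, noise_scale=scale)


def generate_env(config: EnvGenConfig, grid: EqualAreaGrid) -> dict[str, np.ndarray]:
    """Per-cell environmental layers with linear latitudinal trends + noise.

    Each layer is intercept + slope·(latitude − lat_ref) + Gaussian
    noise at the cell centroid. With zero noise the correlation with
    latitude is exactly ±1 per the configured slope sign; as noise
    grows, |r_l| shrinks toward 0.
    """
    rng = np.random.default_rng(config.seed)
    _, lat = grid.centroids_geographic()
    layers = {}
    for name, spec in config.variables.items():
        noise = config.noise_scale * spec.noise_sd * rng.standard_normal(grid.shape)
        layers[name] = spec.intercept + spec.slope * (lat - config.lat_ref) + noise
    return layers
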