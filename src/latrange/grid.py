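"""Equal-area gridding of species ranges and mean range-size mapping.

Ranges are rasterized onto square cells (default 100 km) in an Albers
equal-area conic projection (spherical formulas; all cells therefore
have identical area in projected space). A cell is occupied by a
species when the range geometry covers the cell's centroid; per cell
the arithmetic mean of the latitudinal extents of occupying species
gives the range-size map. Cells with less than half their area on land
are excluded as coastal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from latrange.ranges import ConfigurationError, ValidationError

EARTH_RADIUS_KM = 6371.0072


@dataclass(frozen=True)
class AlbersEqualArea:
    """Albers equal-area conic projection on a sphere (coordinates in km).

    Defaults are standard parallels and origin suited to a China-extent
    domain (18–54° N, 73–135° E); all parameters are configurable.
    """

    lat_1: float = 25.0
    lat_2: float = 47.0
    lat_0: float = 36.0
    lon_0: float = 104.0
    radius: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        n = 0.5 * (math.sin(math.radians(self.lat_1)) + math.sin(math.radians(self.lat_2)))
        if n == 0:
            raise ConfigurationError(
                "standard parallels symmetric about the equator are degenerate"
            )

    @property
    def _n(self) -> float:
        return 0.5 * (math.sin(math.radians(self.lat_1)) + math.sin(math.radians(self.lat_2)))

    @property
    def _C(self) -> float:
        s1 = math.sin(math.radians(self.lat_1))
        return math.cos(math.radians(self.lat_1)) ** 2 + 2 * self._n * s1

    def _rho(self, lat):
        return self.radius * np.sqrt(self._C - 2 * self._n * np.sin(np.radians(lat))) / self._n

    def forward(self, lon, lat):
        """Geographic (degrees) -> projected (km)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        n = self._n
        rho = self._rho(lat)
        rho0 = self._rho(self.lat_0)
        theta = np.radians(n * (lon - self.lon_0))
        return rho * np.sin(theta), rho0 - rho * np.cos(theta)

    def inverse(self, x, y):
        """Projected (km) -> geographic (degrees)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = self._n
        rho0 = self._rho(self.lat_0)
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(x, rho0 - y)
        lat = np.degrees(np.arcsin((self._C - (rho * n / self.radius) ** 2) / (2 * n)))
        lon = self.lon_0 + np.degrees(theta) / n
        return lon, lat


@dataclass(frozen=True)
class FineField:
    """A fine-resolution gridded field in projected space.

    ``values[i, j]`` sits at centre (x0 + (j+0.5)·px, y0 + (i+0.5)·px);
    row 0 is the southernmost row. Used for landmasks and environmental
    layers before aggregation to analysis cells.
    """

    values: np.ndarray  # (ny, nx)
    x0: float  # west edge, km
    y0: float  # south edge, km
    pixel_size: float  # km

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.y0 + (np.arange(ny) + 0.5) * self.pixel_size
        return xs, ys


@dataclass(frozen=True)
class EqualAreaGrid:
    """Square analysis cells in an equal-area projection.

    ``mask`` marks cells excluded from analysis (True = excluded); it is
    populated by :func:`exclude_coastal`.
    """

    projection: AlbersEqualArea
    cell_size: float  # km
    x0: float
    y0: float
    nx: int
    ny: int
    land_fraction: np.ndarray  # (ny, nx)
    mask: np.ndarray = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            object.__setattr__(self, "mask", np.zeros((self.ny, self.nx), dtype=bool))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def centroids_projected(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def centroids_geographic(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (ny, nx) for cell centroids."""
        X, Y = self.centroids_projected()
        return self.projection.inverse(X, Y)

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        j = int(math.floor((x - self.x0) / self.cell_size))
        i = int(math.floor((y - self.y0) / self.cell_size))
        if 0 <= i < self.ny and 0 <= j < self.nx:
            return i, j
        return None


def _cell_indices(grid: EqualAreaGrid, xs: np.ndarray, ys: np.ndarray):
    J = np.floor((xs - grid.x0) / grid.cell_size).astype(int)
    I = np.floor((ys - grid.y0) / grid.cell_size).astype(int)
    return I, J


def _aggregate(grid: EqualAreaGrid, fld: FineField, how: str) -> np.ndarray:
    """Per-cell statistic of fine pixels whose centers fall in the cell."""
    xs, ys = fld.centers
    J1 = np.floor((xs - grid.x0) / grid.cell_size).astype(int)
    I1 = np.floor((ys - grid.y0) / grid.cell_size).astype(int)
    valid_j = (J1 >= 0) & (J1 < grid.nx)
    valid_i = (I1 >= 0) & (I1 < grid.ny)
    vals = fld.values[np.ix_(valid_i, valid_j)].astype(float)
    I = I1[valid_i]
    J = J1[valid_j]
    flat = (I[:, None] * grid.nx + J[None, :]).ravel()
    v = vals.ravel()
    ncell = grid.n_cells
    count = np.bincount(flat, minlength=ncell).astype(float)
    if how == "mean":
        s = np.bincount(flat, weights=v, minlength=ncell)
        with np.errstate(invalid="ignore"):
            out = np.where(count > 0, s / np.maximum(count, 1), np.nan)
    elif how == "range":
        mx = np.full(ncell, -np.inf)
        mn = np.full(ncell, np.inf)
        np.maximum.at(mx, flat, v)
        np.minimum.at(mn, flat, v)
        out = np.where(count > 0, mx - mn, np.nan)
    else:
        raise ConfigurationError(f"unknown statistic {how!r}")
    return out.reshape(grid.shape)


def projected_extent(
    bbox: tuple[float, float, float, float],
    projection: AlbersEqualArea,
    cell_size: float,
) -> tuple[float, float, int, int]:
    """Cell-aligned projected extent (x0, y0, nx, ny) covering a
    geographic bbox (lat_min, lat_max, lon_min, lon_max)."""
    if cell_size <= 0:
        raise ConfigurationError("cell_size must be positive")
    lat_min, lat_max, lon_min, lon_max = bbox
    mid_lon = (lon_min + lon_max) / 2
    corner_lons = np.array([lon_min, lon_max, lon_min, lon_max, mid_lon, mid_lon])
    corner_lats = np.array([lat_min, lat_min, lat_max, lat_max, lat_max, lat_min])
    cx, cy = projection.forward(corner_lons, corner_lats)
    x0 = cell_size * math.floor(cx.min() / cell_size)
    y0 = cell_size * math.floor(cy.min() / cell_size)
    nx = int(math.ceil((cx.max() - x0) / cell_size))
    ny = int(math.ceil((cy.max() - y0) / cell_size))
    return x0, y0, nx, ny


def build_grid(
    bbox: tuple[float, float, float, float],
    landmask: FineField,
    cell_size: float = 100.0,
    projection: AlbersEqualArea | None = None,
) -> EqualAreaGrid:
    """Build the analysis grid over a geographic bbox and compute land fractions.

    ``bbox`` is (lat_min, lat_max, lon_min, lon_max) in degrees. Cell
    edges are snapped to multiples of ``cell_size`` in projected space;
    ``land_fraction`` is the fraction of fine landmask pixels (pixel
    centers) inside each cell that are land. The landmask must cover the
    bbox.
    """
    if projection is None:
        projection = AlbersEqualArea()
    x0, y0, nx, ny = projected_extent(bbox, projection, cell_size)
    mask_x0, mask_y0 = landmask.x0, landmask.y0
    mask_x1 = mask_x0 + landmask.values.shape[1] * landmask.pixel_size
    mask_y1 = mask_y0 + landmask.values.shape[0] * landmask.pixel_size
    if mask_x0 > x0 or mask_y0 > y0 or mask_x1 < x0 + nx * cell_size or mask_y1 < y0 + ny * cell_size:
        raise ConfigurationError("landmask does not cover the grid extent")
    grid = EqualAreaGrid(
        projection=projection, cell_size=cell_size,
        x0=x0, y0=y0, nx=nx, ny=ny,
        land_fraction=np.zeros((ny, nx)),
    )
    lf = _aggregate(grid, replace(landmask, values=landmask.values.astype(float)), "mean")
    lf = np.nan_to_num(lf, nan=0.0)
    return replace(grid, land_fraction=lf)


def exclude_coastal(grid: EqualAreaGrid, threshold: float = 0.5) -> tuple[EqualAreaGrid, int]:
    """Mask cells whose land fraction is strictly below ``threshold``.

    A cell at exactly the threshold (e.g. 0.50 with the default) is
    retained. Returns the masked grid and the number of excluded cells.
    """
    mask = grid.land_fraction < threshold
    return replace(grid, mask=mask), int(mask.sum())


@dataclass(frozen=True)
class LatLonBox:
    """Axis-aligned geographic range geometry (bounds inclusive)."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def covers(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        return (
            (lat >= self.lat_min) & (lat <= self.lat_max)
            & (lon >= self.lon_min) & (lon <= self.lon_max)
        )


@dataclass(frozen=True)
class OccupancyRaster:
    """The set of grid cells a species occupies, as (row, col) indices."""

    species_id: str
    cells: frozenset[tuple[int, int]]


def rasterize_range(
    species_id: str,
    geometry,
    grid: EqualAreaGrid,
) -> OccupancyRaster:
    """Occupancy by the centroid rule: a cell is occupied iff the range
    geometry covers the cell centroid's geographic coordinates.

    ``geometry`` is a :class:`LatLonBox` or any shapely geometry in
    (lon, lat) coordinates. Masked cells are never occupied. An empty
    geometry yields an empty raster.
    """
    lon, lat = grid.centroids_geographic()
    if isinstance(geometry, LatLonBox):
        occ = geometry.covers(lon, lat)
    else:
        from shapely import covers, points

        if geometry.is_empty:
            import warnings

            warnings.warn(f"{species_id}: empty range geometry", stacklevel=2)
            return OccupancyRaster(species_id, frozenset())
        occ = covers(geometry, points(np.stack([lon.ravel(), lat.ravel()], axis=1)))
        occ = occ.reshape(grid.shape)
    occ = occ & ~grid.mask
    cells = frozenset(zip(*map(lambda a: a.tolist(), np.nonzero(occ))))
    return OccupancyRaster(species_id, cells)


@dataclass(frozen=True)
class RangeSizeMap:
    """Per-cell mean latitudinal extent and species count."""

    grid: EqualAreaGrid
    mean_extent: np.ndarray  # NaN where empty or masked
    n_species: np.ndarray

    @property
    def empty(self) -> np.ndarray:
        return (self.n_species == 0) & ~self.grid.mask


def mean_range_map(
    rasters: Sequence[OccupancyRaster],
    extents: Mapping[str, float],
    grid: EqualAreaGrid,
) -> RangeSizeMap:
    """Arithmetic mean of the latitudinal extents of species occupying
    each unmasked cell; cells with no species are NaN (flagged empty)."""
    missing = [r.species_id for r in rasters if r.species_id not in extents]
    if missing:
        raise ValidationError(f"no extent for species: {', '.join(missing[:5])}")
    total = np.zeros(grid.shape)
    count = np.zeros(grid.shape, dtype=int)
    for r in rasters:
        e = float(extents[r.species_id])
        for i, j in r.cells:
            if not grid.mask[i, j]:
                total[i, j] += e
                count[i, j] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    mean[grid.mask] = np.nan
    return RangeSizeMap(grid=grid, mean_extent=mean, n_species=count)


def aggregate_env_to_grid(
    fld: FineField,
    grid: EqualAreaGrid,
    statistic: Literal["mean", "range"] = "mean",
) -> np.ndarray:
    """Aggregate a fine-resolution field to analysis cells.

    ``mean`` for ordinary climate/energy layers; ``range`` (max − min)
    for within-cell heterogeneity such as altitude range. Cells with no
    contributing fine pixels are NaN.
    """
    return _aggregate(grid, fld, statistic)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text raster interchange)

def write_ascii_grid(
    values: np.ndarray, x0: float, y0: float, cellsize: float,
    path: str | Path, nodata: float = -9999.0,
) -> None:
    """Write a 2-D field (row 0 = south) as an ESRI ASCII grid."""
    arr = np.where(np.isfinite(values), values, nodata)
    ny, nx = arr.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {x0}\nyllcorner {y0}\n"
        f"cellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI convention: first data row is the northernmost
        np.savetxt(fh, arr[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path) -> FineField:
    """Read an ESRI ASCII grid into a :class:`FineField` (NODATA -> NaN)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    nodata = header.get("nodata_value")
    if nodata is not None:
        data[data == nodata] = np.nan
    return FineField(
        values=data,
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        pixel_size=header["cellsize"],
    )
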