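"""Core data model: species latitudinal ranges, band systems, extent summaries.

A species' one-dimensional distribution is reduced to its latitudinal
terminals (``lat_min``, ``lat_max``); the derived mid-point and extent
are the raw material for every downstream estimator. Latitudinal bands
are half-open intervals of fixed width tiling the study domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


class ConfigurationError(ValueError):
    """Raised when an analysis configuration is infeasible."""


@dataclass(frozen=True)
class Domain:
    """A closed latitudinal study domain [lat_lo, lat_hi], decimal degrees."""

    lat_lo: float
    lat_hi: float

    def __post_init__(self) -> None:
        if not self.lat_lo < self.lat_hi:
            raise ConfigurationError(
                f"domain requires lat_lo < lat_hi, got [{self.lat_lo}, {self.lat_hi}]"
            )

    @property
    def width(self) -> float:
        return self.lat_hi - self.lat_lo

    @property
    def center(self) -> float:
        return 0.5 * (self.lat_lo + self.lat_hi)

    def contains(self, lat: float) -> bool:
        return self.lat_lo <= lat <= self.lat_hi


@dataclass(frozen=True)
class SpeciesRange:
    """One species' latitudinal extent: southern and northern terminals."""

    species_id: str
    lat_min: float
    lat_max: float

    def validate(self, domain: Domain | None = None) -> "SpeciesRange":
        if not np.isfinite(self.lat_min) or not np.isfinite(self.lat_max):
            raise ValidationError(f"{self.species_id}: non-finite latitude bound")
        if self.lat_min > self.lat_max:
            raise ValidationError(
                f"{self.species_id}: lat_min {self.lat_min} > lat_max {self.lat_max}"
            )
        if domain is not None and not (
            domain.contains(self.lat_min) and domain.contains(self.lat_max)
        ):
            raise ValidationError(
                f"{self.species_id}: range [{self.lat_min}, {self.lat_max}] "
                f"outside domain [{domain.lat_lo}, {domain.lat_hi}]"
            )
        return self


@dataclass(frozen=True)
class RangeStats:
    """Mid-point and latitudinal extent derived from a species range."""

    species_id: str
    midpoint: float
    extent: float


def derive_stats(r: SpeciesRange, domain: Domain | None = None) -> RangeStats:
    """Mid-point = mean of the terminals; extent = their difference.

    Exact arithmetic on the given bounds: the original terminals are
    recoverable as midpoint ± extent/2.
    """
    r.validate(domain)
    return RangeStats(
        species_id=r.species_id,
        midpoint=(r.lat_min + r.lat_max) / 2.0,
        extent=r.lat_max - r.lat_min,
    )


@dataclass(frozen=True)
class BandSystem:
    """Contiguous half-open latitudinal bands [lo, hi) covering a domain.

    Bands are anchored at ``anchor`` (a latitude <= domain.lat_lo) and have
    fixed width; exactly those bands intersecting the domain are kept. By
    the half-open convention a latitude on a band boundary belongs to the
    upper band, except the domain's top latitude which closes into the
    topmost band.
    """

    domain: Domain
    band_width: float
    anchor: float
    edges: tuple[float, ...] = field(default=(), compare=False)

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1

    @property
    def bands(self) -> list[tuple[float, float]]:
        return list(zip(self.edges[:-1], self.edges[1:]))

    @property
    def centers(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    def band_index(self, lat: float) -> int:
        """Index of the band containing ``lat`` under the half-open rule."""
        if not self.domain.contains(lat):
            raise ValidationError(
                f"latitude {lat} outside domain "
                f"[{self.domain.lat_lo}, {self.domain.lat_hi}]"
            )
        if lat >= self.edges[-2]:  # top band closes at the domain top
            return self.n_bands - 1
        k = int(math.floor((lat - self.anchor) / self.band_width))
        return k - self._k0

    @property
    def _k0(self) -> int:
        return int(math.floor((self.domain.lat_lo - self.anchor) / self.band_width))


def make_band_system(
    domain: Domain, band_width: float = 5.0, anchor: float | None = None
) -> BandSystem:
    """Tile a domain with fixed-width half-open bands.

    ``anchor`` defaults to the largest multiple of ``band_width`` not above
    ``domain.lat_lo`` — e.g. an 18–54° domain with 5° bands anchors at 15°,
    giving the conventional eight bands 15–20 … 50–55.
    """
    if band_width <= 0:
        raise ConfigurationError(f"band_width must be positive, got {band_width}")
    if anchor is None:
        anchor = band_width * math.floor(domain.lat_lo / band_width)
    if anchor > domain.lat_lo:
        raise ConfigurationError(
            f"anchor {anchor} must not exceed domain.lat_lo {domain.lat_lo}"
        )
    k0 = int(math.floor((domain.lat_lo - anchor) / band_width))
    # last band is the one whose half-open interval contains lat_hi, or the
    # band below when lat_hi sits exactly on an edge (top closure).
    k1 = int(math.floor((domain.lat_hi - anchor) / band_width))
    if anchor + k1 * band_width == domain.lat_hi:
        k1 -= 1
    edges = tuple(anchor + k * band_width for k in range(k0, k1 + 2))
    return BandSystem(domain=domain, band_width=band_width, anchor=anchor, edges=edges)


@dataclass(frozen=True)
class DistributionSummary:
    """Moments and histogram of a sample of latitudinal extents."""

    n: int
    mean: float
    sd: float
    median: float
    skewness: float  # adjusted Fisher-Pearson; NaN when undefined
    hist_edges: tuple[float, ...]
    hist_counts: tuple[int, ...]


@dataclass(frozen=True)
class ExtentSummary:
    """Summary of raw extents plus the log10-transformed variant."""

    raw: DistributionSummary
    log10: DistributionSummary
    n_zero_excluded: int  # zero-extent species excluded from the log10 variant


def _summarize(values: np.ndarray, bins) -> DistributionSummary:
    counts, edges = np.histogram(values, bins=bins)
    if values.size >= 3 and np.std(values) > 0:
        skew = float(sps.skew(values, bias=False))
    else:
        skew = float("nan")
    return DistributionSummary(
        n=int(values.size),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)),
        median=float(np.median(values)),
        skewness=skew,
        hist_edges=tuple(float(e) for e in edges),
        hist_counts=tuple(int(c) for c in counts),
    )


def summarize_extents(
    ranges: Sequence[SpeciesRange],
    bins=10,
    log10_bins=10,
) -> ExtentSummary:
    """Distributional summary of latitudinal extents (raw and log10 scale).

    Sample SD uses the n−1 denominator; skewness is the bias-corrected
    (adjusted Fisher–Pearson) statistic, reported as NaN when undefined
    (fewer than three values, or zero variance). Zero-extent species are
    excluded from the log10 variant and counted in ``n_zero_excluded``.
    """
    if len(ranges) < 2:
        raise ValidationError("summarize_extents requires at least 2 species")
    extents = np.array([derive_stats(r).extent for r in ranges], dtype=float)
    raw = _summarize(extents, bins)
    pos = extents[extents > 0]
    if pos.size < 2:
        raise ValidationError("log10 summary requires at least 2 nonzero extents")
    log10 = _summarize(np.log10(pos), log10_bins)
    return ExtentSummary(raw=raw, log10=log10, n_zero_excluded=int((extents == 0).sum()))


def count_in_extent_classes(
    ranges: Sequence[SpeciesRange],
    classes: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Count species whose extent falls in each half-open class [lo, hi).

    Use ``-inf``/``inf`` bounds for open-ended classes. Percentages are of
    the total species count, rounded to one decimal.
    """
    for lo, hi in classes:
        if not lo < hi:
            raise ValidationError(f"malformed extent class [{lo}, {hi})")
    extents = np.array([derive_stats(r).extent for r in ranges], dtype=float)
    n = len(ranges)
    rows = []
    for lo, hi in classes:
        count = int(((extents >= lo) & (extents < hi)).sum())
        pct = round(100.0 * count / n, 1) if n else 0.0
        rows.append({"class_lo": lo, "class_hi": hi, "count": count, "percent": pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: species ranges as delimited text with header species_id,lat_min,lat_max

RANGE_COLUMNS = ["species_id", "lat_min", "lat_max"]


def read_ranges(path: str | Path, domain: Domain | None = None) -> list[SpeciesRange]:
    """Read species ranges from CSV (``species_id,lat_min,lat_max``)."""
    df = pd.read_csv(path)
    missing = [c for c in RANGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: no species records")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        try:
            r = SpeciesRange(str(row.species_id), float(row.lat_min), float(row.lat_max))
            r.validate(domain)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}:{i}: {exc}") from exc
        out.append(r)
    return out


def write_ranges(ranges: Iterable[SpeciesRange], path: str | Path) -> None:
    pd.DataFrame(
        [(r.species_id, r.lat_min, r.lat_max) for r in ranges],
        columns=RANGE_COLUMNS,
    ).to_csv(path, index=False)
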