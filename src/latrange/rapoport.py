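"""The four classical Rapoport's-rule estimators and trend-fit selection.

Stevens' method averages extents over every species whose range overlaps
a band (bands are therefore non-independent); the mid-point method
assigns each species once, to the band holding its range mid-point;
Pagel's method assigns by the northern terminus; the cross-species
method regresses extent on mid-point with no binning at all. Band
profiles are fitted with linear and second-order polynomial OLS and the
better model is selected by adjusted R² (raw R² cannot prefer the
nested linear model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from latrange.ranges import (
    BandSystem,
    Domain,
    SpeciesRange,
    ValidationError,
    derive_stats,
)

ProfileMethod = Literal["stevens", "midpoint", "pagel", "cross_species"]


@dataclass(frozen=True)
class BandProfile:
    """Per-band species counts and mean/SD of latitudinal extent.

    Bands with no member species carry NaN means (never zero).
    """

    method: str
    band_system: BandSystem
    n_species: np.ndarray  # (n_bands,) int
    mean_extent: np.ndarray  # (n_bands,) float, NaN where empty
    sd_extent: np.ndarray  # (n_bands,) float, NaN where n < 2

    @property
    def band_centers(self) -> np.ndarray:
        return self.band_system.centers

    def to_frame(self) -> pd.DataFrame:
        bands = self.band_system.bands
        return pd.DataFrame(
            {
                "method": self.method,
                "band_lo": [b[0] for b in bands],
                "band_hi": [b[1] for b in bands],
                "n": self.n_species,
                "mean_extent": self.mean_extent,
                "sd_extent": self.sd_extent,
            }
        )


def _profile_from_membership(
    method: str, bands: BandSystem, members: list[list[float]]
) -> BandProfile:
    n = np.array([len(m) for m in members], dtype=int)
    mean = np.array([np.mean(m) if m else np.nan for m in members], dtype=float)
    sd = np.array(
        [np.std(m, ddof=1) if len(m) >= 2 else np.nan for m in members], dtype=float
    )
    return BandProfile(method, bands, n, mean, sd)


def _check_nonempty(ranges: Sequence[SpeciesRange]) -> None:
    if not ranges:
        raise ValidationError("profile requires at least one species")


def stevens_profile(ranges: Sequence[SpeciesRange], bands: BandSystem) -> BandProfile:
    """Stevens' method: a species contributes to every band it overlaps.

    Membership requires nonzero interval overlap; a zero-extent species
    counts in the single band containing its point. Per-band counts sum
    to at least the species count (ranges spanning several bands are
    counted once per band).
    """
    _check_nonempty(ranges)
    members: list[list[float]] = [[] for _ in range(bands.n_bands)]
    for r in ranges:
        st = derive_stats(r, bands.domain)
        if st.extent == 0:
            members[bands.band_index(r.lat_min)].append(st.extent)
            continue
        for i, (lo, hi) in enumerate(bands.bands):
            if max(r.lat_min, lo) < min(r.lat_max, hi):
                members[i].append(st.extent)
    return _profile_from_membership("stevens", bands, members)


def midpoint_profile(ranges: Sequence[SpeciesRange], bands: BandSystem) -> BandProfile:
    """Mid-point method: each species assigned to the band of its mid-point."""
    _check_nonempty(ranges)
    members: list[list[float]] = [[] for _ in range(bands.n_bands)]
    for r in ranges:
        st = derive_stats(r, bands.domain)
        members[bands.band_index(st.midpoint)].append(st.extent)
    return _profile_from_membership("midpoint", bands, members)


def pagel_profile(ranges: Sequence[SpeciesRange], bands: BandSystem) -> BandProfile:
    """Pagel's method: each species assigned to the band of its northern limit."""
    _check_nonempty(ranges)
    members: list[list[float]] = [[] for _ in range(bands.n_bands)]
    for r in ranges:
        st = derive_stats(r, bands.domain)
        members[bands.band_index(r.lat_max)].append(st.extent)
    return _profile_from_membership("pagel", bands, members)


def cross_species_table(ranges: Sequence[SpeciesRange]) -> pd.DataFrame:
    """One (midpoint, extent) point per species, no binning."""
    _check_nonempty(ranges)
    stats = [derive_stats(r) for r in ranges]
    return pd.DataFrame(
        {
            "species_id": [s.species_id for s in stats],
            "midpoint": [s.midpoint for s in stats],
            "extent": [s.extent for s in stats],
        }
    )


@dataclass(frozen=True)
class TrendFit:
    """An OLS polynomial trend of degree 1 (linear) or 2 (quadratic)."""

    form: Literal["linear", "quadratic"]
    intercept: float
    slope: float
    quad: float | None
    r2: float
    adj_r2: float
    p_value: float  # model F-test
    n: int
    slope_se: float
    slope_p: float

    @property
    def coefficients(self) -> tuple[float, ...]:
        if self.form == "linear":
            return (self.intercept, self.slope)
        return (self.intercept, self.slope, self.quad)

    def slope_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-approximation confidence interval for the linear slope."""
        from scipy import stats as sps

        k = 2 if self.form == "linear" else 3
        t = sps.t.ppf(1 - alpha / 2, self.n - k)
        return (self.slope - t * self.slope_se, self.slope + t * self.slope_se)


class FittingError(ValueError):
    """Raised for degenerate or underdetermined regression designs."""


def _ols_poly(x: np.ndarray, y: np.ndarray, degree: int) -> TrendFit:
    form = "linear" if degree == 1 else "quadratic"
    cols = {"x": x}
    if degree == 2:
        cols["x2"] = x**2
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise FittingError(f"degenerate design for {form} fit (collinear predictors)")
    res = sm.OLS(y, X).fit()
    return TrendFit(
        form=form,
        intercept=float(res.params["const"]),
        slope=float(res.params["x"]),
        quad=float(res.params["x2"]) if degree == 2 else None,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        p_value=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else float("nan"),
        n=int(res.nobs),
        slope_se=float(res.bse["x"]),
        slope_p=float(res.pvalues["x"]),
    )


def fit_trend(
    x: np.ndarray,
    y: np.ndarray,
    forms: Sequence[str] = ("linear", "quadratic"),
) -> tuple[TrendFit, dict[str, TrendFit]]:
    """OLS fits of each requested form, with adjusted-R² model selection.

    NaN pairs (e.g. empty bands) are dropped pairwise. Returns the
    selected fit and the dict of all candidate fits. Selection by
    adjusted R²; raw R² is reported on every candidate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    candidates: dict[str, TrendFit] = {}
    for form in forms:
        degree = {"linear": 1, "quadratic": 2}[form]
        if len(x) < degree + 2:
            continue
        candidates[form] = _ols_poly(x, y, degree)
    if not candidates:
        raise FittingError(
            f"too few points (n={len(x)}) for any requested form {list(forms)}"
        )
    selected = max(candidates.values(), key=lambda f: f.adj_r2)
    return selected, candidates


Verdict = Literal["supported", "not_supported", "hump_shaped"]


def rapoport_verdict(
    fit: TrendFit, domain: Domain | None = None, alpha: float = 0.05
) -> Verdict:
    """Classify a fitted latitude/range-size trend.

    ``supported``: linear form selected with a significantly positive
    slope (Rapoport's rule). ``hump_shaped``: quadratic selected with a
    negative curvature and an interior maximum (inside the domain when
    one is given). Anything else: ``not_supported``.
    """
    if fit.form == "linear":
        if fit.slope > 0 and fit.p_value < alpha:
            return "supported"
        return "not_supported"
    if fit.quad is not None and fit.quad < 0:
        peak = -fit.slope / (2 * fit.quad)
        if domain is None or domain.lat_lo < peak < domain.lat_hi:
            return "hump_shaped"
    return "not_supported"
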