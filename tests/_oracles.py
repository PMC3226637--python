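"""Independent oracles for the estimator and null-model tests.

Deliberately naive: exhaustive per-species/per-band membership
enumeration for the band estimators, and subset enumeration over
numerically integrated per-band placement probabilities for the
mid-domain null. These never share code with the implementations they
check.
"""

from itertools import combinations

import numpy as np
from scipy import integrate

from latrange.ranges import BandSystem, Domain, SpeciesRange


def _band_of_point(bands: BandSystem, lat: float) -> int:
    """Half-open membership with top closure, by linear scan."""
    intervals = bands.bands
    for i, (lo, hi) in enumerate(intervals):
        if lo <= lat < hi:
            return i
    if lat == bands.domain.lat_hi:
        for i, (lo, hi) in enumerate(intervals):
            if lo <= lat <= hi:
                return i
    raise AssertionError(f"latitude {lat} not in any band")


def brute_force_profile(
    ranges: list[SpeciesRange], bands: BandSystem, method: str
) -> tuple[np.ndarray, np.ndarray]:
    """(counts, means) by exhaustive membership enumeration."""
    members = [[] for _ in bands.bands]
    for r in ranges:
        extent = r.lat_max - r.lat_min
        if method == "stevens":
            if extent == 0:
                members[_band_of_point(bands, r.lat_min)].append(extent)
            else:
                for i, (lo, hi) in enumerate(bands.bands):
                    overlap = min(r.lat_max, hi) - max(r.lat_min, lo)
                    if overlap > 0:
                        members[i].append(extent)
        elif method == "midpoint":
            members[_band_of_point(bands, (r.lat_min + r.lat_max) / 2)].append(extent)
        elif method == "pagel":
            members[_band_of_point(bands, r.lat_max)].append(extent)
        else:
            raise ValueError(method)
    counts = np.array([len(m) for m in members])
    means = np.array([np.mean(m) if m else np.nan for m in members])
    return counts, means


def band_probability(extent: float, band: tuple[float, float], domain: Domain) -> float:
    """P(mid-point lands in the band) for uniform feasible placement,
    by numerical integration of the uniform mid-point density."""
    lo_f = domain.lat_lo + extent / 2
    hi_f = domain.lat_hi - extent / 2
    if hi_f <= lo_f:  # full-domain extent: mid-point forced to the centre
        c = domain.center
        a, b = band
        top = b == domain.lat_hi or (b > domain.lat_hi)
        return float(a <= c < b or (top and c == b))
    density = 1.0 / (hi_f - lo_f)
    a = max(band[0], lo_f)
    b = min(band[1], hi_f)
    if b <= a:
        return 0.0
    val, _ = integrate.quad(lambda m: density, a, b)
    return float(val)


def exact_conditional_band_mean(
    extents: list[float], band: tuple[float, float], domain: Domain
) -> float:
    """E[band mean extent | band non-empty] under independent uniform
    feasible placement, by enumeration over occupancy subsets."""
    ps = [band_probability(e, band, domain) for e in extents]
    idx = range(len(extents))
    total_p = 0.0
    total = 0.0
    for k in range(1, len(extents) + 1):
        for subset in combinations(idx, k):
            p = 1.0
            for i in idx:
                p *= ps[i] if i in subset else (1 - ps[i])
            if p == 0:
                continue
            total_p += p
            total += p * np.mean([extents[i] for i in subset])
    if total_p == 0:
        return float("nan")
    return total / total_p
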