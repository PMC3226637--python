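import numpy as np
import pytest

from latrange.ranges import Domain, SpeciesRange, make_band_system


@pytest.fixture
def toy_ranges():
    """Three species on a 0–15° domain, used throughout the estimator tests."""
    return [
        SpeciesRange("A", 0.0, 10.0),
        SpeciesRange("B", 2.0, 4.0),
        SpeciesRange("C", 6.0, 14.0),
    ]


@pytest.fixture
def toy_bands():
    return make_band_system(Domain(0.0, 15.0), 5.0, anchor=0.0)


@pytest.fixture
def china_domain():
    return Domain(18.0, 54.0)


def random_instance(rng: np.random.Generator, max_species: int = 50):
    """A random domain, band system and species set for oracle checks."""
    lo = rng.uniform(-60, 40)
    width = rng.uniform(10, 60)
    domain = Domain(lo, lo + width)
    band_width = rng.uniform(2, 10)
    anchor = lo - rng.uniform(0, band_width)
    bands = make_band_system(domain, band_width, anchor=anchor)
    n = rng.integers(1, max_species + 1)
    a = rng.uniform(lo, lo + width, size=n)
    b = rng.uniform(lo, lo + width, size=n)
    lat_min, lat_max = np.minimum(a, b), np.maximum(a, b)
    if n >= 3:  # include degenerate point ranges sometimes
        lat_max[0] = lat_min[0]
    ranges = [
        SpeciesRange(f"s{i}", float(x), float(y))
        for i, (x, y) in enumerate(zip(lat_min, lat_max))
    ]
    return domain, bands, ranges
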