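import numpy as np
import pytest

from soilspec import BandCatalog, default_grid, generate_library
from soilspec.synth import Band, DEFAULT_CATALOG


def noise_free_catalog(**overrides) -> BandCatalog:
    """Catalog with all stochastic terms switched off."""
    base = dict(
        scan_noise_sd=0.0, baseline_jitter_sd=0.0, lab_noise_sd=0.0,
    )
    base.update(overrides)
    return BandCatalog(**base)


def linear_catalog() -> BandCatalog:
    """Noise-free catalog whose property -> spectrum map is exactly linear
    (no sand enhancement or clay masking of the SOC band)."""
    return noise_free_catalog(sand_enhancement=0.0, clay_masking=0.0)


@pytest.fixture(scope="session")
def small_mineral_library():
    """40 mineral samples, two scans, 20% duplicate analyses."""
    return generate_library(40, "mineral", seed=11, duplicate_fraction=0.2)


@pytest.fixture(scope="session")
def small_organic_library():
    return generate_library(15, "organic", seed=5)


@pytest.fixture(scope="session")
def grid():
    return default_grid()
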