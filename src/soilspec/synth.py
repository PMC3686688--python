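"""Synthetic soil spectral libraries with known property -> spectrum structure.

The generator emulates the statistical and spectral structure of a
continental-scale topsoil library (the LUCAS survey is the template): a
right-skewed mineral SOC distribution, a separate high-SOC organic subset,
land-cover strata, duplicate instrument scans and duplicate laboratory
analyses, and the dominant Vis-NIR absorption features of soil —

* an organic-matter feature centred near 620 nm whose depth grows with SOC,
* hydroxyl/water features at 1415, 1455, 1915 and 2207 nm that grow with clay,
* iron-oxide electronic transitions near 540, 640 and 900 nm,
* sand-driven scattering that lowers the baseline albedo and *enhances* the
  SOC feature, while clay progressively *masks* it.

Spectra are built in absorbance following a Beer-Lambert-like additive model

    A(lambda) = baseline(sand) + splice_step(lambda)
                + sum_b gain_b * x_driver(b) * enh_b(sand, clay) * G(lambda; c_b, w_b)
                + scan noise,

then converted to reflectance R = 10^(-A).  Every generator is a pure
function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import (
    PROPERTY_COLUMNS,
    SpectralLibrary,
    default_grid,
)
from .errors import SoilSpecError, UnknownSubsetError

SUBSETS = ("cropland", "grassland", "woodland", "mineral", "organic")

# Target moments of the mineral / organic SOC distributions (g C kg^-1).
MINERAL_SOC_MEAN = 29.4
MINERAL_SOC_SD = 28.9
MINERAL_SOC_MAX = 200.0
ORGANIC_SOC_MIN = 156.4
ORGANIC_SOC_MAX = 586.8
ORGANIC_SOC_MEAN = 387.1
ORGANIC_SOC_SD = 101.2

# Texture targets (% of mineral fine earth): clay 18.9 +- 13.0, silt 38.2, sand 42.9.
_TEXTURE_MEANS = np.array([0.189, 0.382, 0.429])
_TEXTURE_CONC = 8.0  # Dirichlet concentration giving clay SD ~= 13 %


# --------------------------------------------------------------------------
# Property sampling
# --------------------------------------------------------------------------

def _truncated_lognormal_params(mean: float, sd: float, upper: float
                                ) -> tuple[float, float]:
    """(mu, sigma) of a lognormal whose truncation to [0, upper] has the
    requested mean and SD.  Solved numerically from the moment equations."""

    def trunc_moments(mu: float, sigma: float) -> tuple[float, float]:
        z = (np.log(upper) - mu) / sigma
        p = stats.norm.cdf(z)
        m1 = np.exp(mu + sigma**2 / 2) * stats.norm.cdf(z - sigma) / p
        m2 = np.exp(2 * mu + 2 * sigma**2) * stats.norm.cdf(z - 2 * sigma) / p
        return m1, np.sqrt(m2 - m1**2)

    def residual(theta):
        m, s = trunc_moments(theta[0], np.exp(theta[1]))
        return [m - mean, s - sd]

    # untruncated moment-matched start
    sigma0 = np.sqrt(np.log1p((sd / mean) ** 2))
    mu0 = np.log(mean) - sigma0**2 / 2
    sol = optimize.fsolve(residual, [mu0, np.log(sigma0)], full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


_MINERAL_LOGNORM = _truncated_lognormal_params(
    MINERAL_SOC_MEAN, MINERAL_SOC_SD, MINERAL_SOC_MAX
)


def _sample_mineral_soc(n: int, rng: np.random.Generator) -> np.ndarray:
    mu, sigma = _MINERAL_LOGNORM
    z_up = (np.log(MINERAL_SOC_MAX) - mu) / sigma
    u = rng.uniform(0.0, stats.norm.cdf(z_up), size=n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _organic_beta_params() -> tuple[float, float]:
    span = ORGANIC_SOC_MAX - ORGANIC_SOC_MIN
    m = (ORGANIC_SOC_MEAN - ORGANIC_SOC_MIN) / span
    v = (ORGANIC_SOC_SD / span) ** 2
    c = m * (1 - m) / v - 1
    return m * c, (1 - m) * c


_ORGANIC_BETA = _organic_beta_params()


def _sample_organic_soc(n: int, rng: np.random.Generator) -> np.ndarray:
    a, b = _ORGANIC_BETA
    span = ORGANIC_SOC_MAX - ORGANIC_SOC_MIN
    return ORGANIC_SOC_MIN + span * rng.beta(a, b, size=n)


def classify_organic(soc: float, clay: float | None = None) -> str:
    """Classify a sample as mineral or organic soil material.

    The organic threshold rises linearly with clay content from 120 g C kg^-1
    at 0 % clay to 180 g C kg^-1 at >= 60 % clay (clay-dependent definition of
    organic soil material); missing clay uses the 120 g C kg^-1 floor.
    """
    if soc < 0 or not np.isfinite(soc):
        raise SoilSpecError(f"soc must be >= 0, got {soc}")
    if clay is None or (isinstance(clay, float) and np.isnan(clay)):
        threshold = 120.0
    else:
        threshold = 120.0 + 60.0 * min(max(clay, 0.0), 60.0) / 60.0
    return "organic" if soc >= threshold else "mineral"


def sample_properties(n: int, subset: str, seed: int) -> pd.DataFrame:
    """Draw ``n`` property rows for a library subset.

    ``subset`` is one of cropland / grassland / woodland (mineral soils under
    one land cover), ``mineral`` (mixed land covers) or ``organic``.
    Deterministic under ``(n, subset, seed)``.
    """
    if n < 1:
        raise SoilSpecError("n must be >= 1")
    if subset not in SUBSETS:
        raise UnknownSubsetError(
            f"unknown subset {subset!r}; expected one of {SUBSETS}"
        )
    rng = np.random.default_rng(seed)
    organic = subset == "organic"

    if organic:
        soc = _sample_organic_soc(n, rng)
        clay = silt = sand = np.full(n, np.nan)
        nitrogen = np.clip(soc / 25.0 * rng.lognormal(0.0, 0.25, n), 0, None)
        caco3 = np.where(rng.random(n) < 0.15, rng.gamma(0.5, 20.0, n), 0.0)
        ph = np.clip(rng.normal(4.5, 0.7, n), 3.0, 10.5)
        cec = np.clip(rng.gamma(2.0, 21.0, n), 0, None)
        land = rng.choice(["woodland", "grassland", "other"], size=n,
                          p=[0.6, 0.25, 0.15])
    else:
        soc = _sample_mineral_soc(n, rng)
        texture = 100.0 * rng.dirichlet(_TEXTURE_CONC * _TEXTURE_MEANS, size=n)
        clay, silt, sand = texture[:, 0], texture[:, 1], texture[:, 2]
        nitrogen = np.clip(soc / 13.4 * rng.lognormal(0.0, 0.25, n), 0, None)
        caco3 = np.where(rng.random(n) < 0.5, rng.gamma(0.45, 120.0, n), 0.0)
        ph = np.clip(rng.normal(6.3, 1.3, n), 3.0, 10.5)
        cec = np.clip(3.0 + 0.45 * clay + 0.12 * soc + rng.gamma(2.0, 2.0, n),
                      0, None)
        if subset == "mineral":
            land = rng.choice(["cropland", "grassland", "woodland"], size=n,
                              p=[0.47, 0.23, 0.30])
        else:
            land = np.full(n, subset, dtype=object)

    return pd.DataFrame({
        "sample_id": [f"{subset[:3]}{seed:04d}-{i:05d}" for i in range(n)],
        "land_cover": land,
        "material": "organic" if organic else "mineral",
        "soc": soc,
        "nitrogen": nitrogen,
        "clay": clay,
        "silt": silt,
        "sand": sand,
        "caco3": caco3,
        "ph": ph,
        "cec": cec,
    })


# --------------------------------------------------------------------------
# Spectrum synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: driver property, centre/width in nm,
    gain in absorbance units per property unit."""

    center: float
    width: float
    driver: str
    gain: float

    def __post_init__(self) -> None:
        if not (400.0 <= self.center <= 2500.0):
            raise SoilSpecError(f"band centre {self.center} nm outside 400-2500")
        if self.width <= 0 or not np.isfinite(self.gain):
            raise SoilSpecError("band width must be > 0 and gain finite")


@dataclass(frozen=True)
class BandCatalog:
    """Absorption bands plus baseline and noise models for the generator.

    ``sand_enhancement`` and ``clay_masking`` act multiplicatively on the
    620 nm SOC band gain: depth scales with
    ``(1 + sand_enhancement * sand/100) / (1 + clay_masking * clay/100)``.
    """

    bands: tuple[Band, ...] = (
        Band(620.0, 90.0, "soc", 2.2e-3),      # organic matter, visible
        Band(1415.0, 18.0, "clay", 1.6e-3),    # clay lattice O-H
        Band(2207.0, 22.0, "clay", 2.4e-3),    # metal-OH combination
        Band(1455.0, 28.0, "clay", 2.0e-3),    # bound water
        Band(1915.0, 32.0, "clay", 3.2e-3),    # bound water
        Band(540.0, 35.0, "cec", 6.0e-4),      # iron-oxide proxy
        Band(640.0, 30.0, "cec", 4.0e-4),
        Band(900.0, 45.0, "cec", 5.0e-4),
        Band(2100.0, 60.0, "nitrogen", 4.0e-3),  # organic N-H/C-H overtones
    )
    albedo_intercept: float = 0.35
    sand_scatter: float = 0.25        # absorbance added at 100 % sand
    splice_offset: float = 0.02       # additive step for bands >= splice_nm
    splice_nm: float = 1100.0
    sand_enhancement: float = 0.8
    clay_masking: float = 1.5
    scan_noise_sd: float = 0.005      # absorbance, per scan per band
    baseline_jitter_sd: float = 0.02  # per-scan flat offset (scatter variability)
    lab_noise_sd: float = 2.0         # g C kg^-1, replicate laboratory analyses

    def validate(self) -> None:
        for b in self.bands:
            Band(b.center, b.width, b.driver, b.gain)
        if self.scan_noise_sd < 0 or self.lab_noise_sd < 0:
            raise SoilSpecError("noise SDs must be >= 0")


DEFAULT_CATALOG = BandCatalog()


def _band_gain(band: Band, row: pd.Series, catalog: BandCatalog) -> float:
    gain = band.gain
    if band.driver == "soc":
        sand = row.get("sand", np.nan)
        clay = row.get("clay", np.nan)
        if np.isfinite(sand):
            gain *= 1.0 + catalog.sand_enhancement * sand / 100.0
        if np.isfinite(clay):
            gain /= 1.0 + catalog.clay_masking * clay / 100.0
    return gain


def spectrum_from_properties(
    row: pd.Series | dict,
    catalog: BandCatalog = DEFAULT_CATALOG,
    seed: int = 0,
    n_scans: int = 2,
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Reflectance scans for one property row, shape ``(n_scans, n_bands)``.

    Raises if a driver property needed with a non-zero gain is negative or
    otherwise outside the generator's support (missing texture is allowed:
    the sand/clay modifiers then drop out, as for organic samples).
    """
    catalog.validate()
    row = pd.Series(row)
    wl = default_grid() if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(seed)

    for band in catalog.bands:
        x = float(row.get(band.driver, np.nan))
        if band.gain != 0.0 and np.isfinite(x) and x < 0:
            raise SoilSpecError(
                f"property {band.driver!r} = {x} outside generator support"
            )

    sand = float(row.get("sand", np.nan))
    absorbance = np.full(wl.shape, catalog.albedo_intercept)
    if np.isfinite(sand):
        absorbance += catalog.sand_scatter * sand / 100.0
    absorbance += np.where(wl >= catalog.splice_nm, catalog.splice_offset, 0.0)

    for band in catalog.bands:
        x = float(row.get(band.driver, np.nan))
        if not np.isfinite(x) or band.gain == 0.0:
            continue
        g = _band_gain(band, row, catalog)
        absorbance += g * x * np.exp(-0.5 * ((wl - band.center) / band.width) ** 2)

    scans = np.repeat(absorbance[None, :], n_scans, axis=0)
    if catalog.baseline_jitter_sd > 0:
        # scatter variability is a sample-level effect: shared by all scans
        scans += rng.normal(0.0, catalog.baseline_jitter_sd)
    if catalog.scan_noise_sd > 0:
        scans += rng.normal(0.0, catalog.scan_noise_sd, size=scans.shape)
    reflectance = 10.0 ** (-scans)
    return np.clip(reflectance, np.finfo(float).tiny, 1.0)


def generate_library(
    n: int,
    subset: str,
    seed: int,
    duplicate_fraction: float = 0.0,
    catalog: BandCatalog = DEFAULT_CATALOG,
    n_scans: int = 2,
    wavelengths: np.ndarray | None = None,
) -> SpectralLibrary:
    """Generate a full synthetic library: properties, scans, lab duplicates.

    The reported ``soc`` column carries laboratory replicate noise
    (``catalog.lab_noise_sd``) on top of the spectrum-driving true value;
    ``ceil(duplicate_fraction * n)`` samples receive a second, independently
    perturbed laboratory analysis, mimicking duplicate reference analyses.
    """
    if not 0.0 <= duplicate_fraction <= 1.0:
        raise SoilSpecError("duplicate_fraction must lie in [0, 1]")
    props = sample_properties(n, subset, seed)
    wl = default_grid() if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))

    true_soc = props["soc"].to_numpy().copy()
    scans = np.empty((n, n_scans, wl.size))
    scan_seeds = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        row = props.iloc[i]
        scans[i] = spectrum_from_properties(
            row, catalog, seed=int(scan_seeds[i]), n_scans=n_scans, wavelengths=wl
        )

    if catalog.lab_noise_sd > 0:
        props["soc"] = np.clip(
            true_soc + rng.normal(0.0, catalog.lab_noise_sd, n), 0.0, None
        )

    n_dup = int(np.ceil(duplicate_fraction * n))
    duplicate_lab: dict[str, float] = {}
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        for i in dup_idx:
            value = true_soc[i] + rng.normal(0.0, catalog.lab_noise_sd)
            duplicate_lab[props.at[i, "sample_id"]] = float(max(value, 0.0))

    return SpectralLibrary(props, wl, scans, duplicate_lab)


__all__ = [
    "SUBSETS",
    "Band",
    "BandCatalog",
    "DEFAULT_CATALOG",
    "classify_organic",
    "sample_properties",
    "spectrum_from_properties",
    "generate_library",
]
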