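"""In-memory containers shared by the pipeline stages.

A :class:`SpectraMatrix` is the working object of the pre-treatment chain:
an ``n_samples x n_bands`` array on a strictly increasing wavelength grid,
tagged with the representation it currently holds (reflectance, absorbance,
derivative, ...) and an append-only provenance trail of the operations that
produced it.  A :class:`SpectralLibrary` bundles the per-sample property
table with raw reflectance scans and optional duplicate laboratory analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError

#: Representations a spectra matrix may carry.
MODES = (
    "reflectance",
    "absorbance",
    "sg_smoothed",
    "sg_first_derivative",
    "snv",
    "continuum_removed",
)

#: Property columns of the library schema, in canonical order.
PROPERTY_COLUMNS = ("soc", "nitrogen", "clay", "silt", "sand", "caco3", "ph", "cec")

#: Metadata columns preceding the properties.
METADATA_COLUMNS = ("sample_id", "land_cover", "material")

LAND_COVERS = ("cropland", "grassland", "woodland", "other")
MATERIALS = ("mineral", "organic")


@dataclass
class SpectraMatrix:
    """Spectra on a shared wavelength grid.

    Parameters
    ----------
    wavelengths : ndarray, shape (n_bands,)
        Strictly increasing wavelength grid in nm.
    values : ndarray, shape (n_samples, n_bands)
        One spectrum per row.
    mode : str
        Current representation, one of :data:`MODES`.
    sample_ids : ndarray of str
        Row labels, aligned with ``values``.
    provenance : list of str
        Append-only record of applied operations with their parameters.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    mode: str = "reflectance"
    sample_ids: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.mode not in MODES:
            raise FormatError(f"unknown spectra mode {self.mode!r}")
        if self.wavelengths.ndim != 1 or self.values.shape[1] != self.wavelengths.size:
            raise FormatError(
                f"values have {self.values.shape[1]} bands but grid has "
                f"{self.wavelengths.size}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("spectra contain non-finite values")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:05d}" for i in range(self.n_samples)])
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if self.sample_ids.size != self.n_samples:
                raise FormatError("sample_ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def evolve(self, *, values=None, wavelengths=None, mode=None, step: str | None = None
               ) -> "SpectraMatrix":
        """Return a copy with updated fields and ``step`` appended to provenance."""
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        return replace(
            self,
            values=self.values if values is None else values,
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            mode=self.mode if mode is None else mode,
            provenance=prov,
        )

    def take(self, indices) -> "SpectraMatrix":
        """Row subset, preserving provenance (no step recorded)."""
        return replace(
            self,
            values=self.values[np.asarray(indices)],
            sample_ids=self.sample_ids[np.asarray(indices)],
            provenance=list(self.provenance),
        )


def default_grid(start: float = 400.0, stop: float = 2499.5, step: float = 0.5
                 ) -> np.ndarray:
    """The instrument wavelength grid: 400.0-2499.5 nm at 0.5 nm (4200 bands)."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass
class SpectralLibrary:
    """A soil spectral library: properties, raw reflectance scans, duplicates.

    ``scans`` has shape ``(n_samples, n_scans, n_bands)``; every scan shares
    the wavelength grid.  ``duplicate_lab`` maps ``sample_id`` to a replicate
    laboratory SOC value (g C kg^-1) for reproducibility analysis.
    """

    properties: pd.DataFrame
    wavelengths: np.ndarray
    scans: np.ndarray
    duplicate_lab: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.scans = np.asarray(self.scans, dtype=float)
        if self.scans.ndim != 3:
            raise FormatError("scans must have shape (n_samples, n_scans, n_bands)")
        if self.scans.shape[2] != self.wavelengths.size:
            raise FormatError("scan band count does not match wavelength grid")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError("wavelength grid must be strictly increasing")
        if np.any(self.scans <= 0) or np.any(self.scans > 1):
            raise FormatError("reflectance scans must lie in (0, 1]")
        missing = [c for c in METADATA_COLUMNS + PROPERTY_COLUMNS
                   if c not in self.properties.columns]
        if missing:
            raise FormatError(f"property table missing columns {missing}")
        if len(self.properties) != self.scans.shape[0]:
            raise FormatError("property table and scans disagree on sample count")
        unknown = set(self.duplicate_lab) - set(self.properties["sample_id"])
        if unknown:
            raise FormatError(f"duplicate ids not in library: {sorted(unknown)[:3]}")

    @property
    def n_samples(self) -> int:
        return self.scans.shape[0]

    @property
    def n_scans(self) -> int:
        return self.scans.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.properties["sample_id"].to_numpy()

    def reflectance(self) -> SpectraMatrix:
        """Mean-of-scans reflectance matrix (no QC; see preprocess for QC)."""
        return SpectraMatrix(
            wavelengths=self.wavelengths,
            values=self.scans.mean(axis=1),
            mode="reflectance",
            sample_ids=self.sample_ids,
            provenance=[f"average_scans(n_scans={self.n_scans}, qc=None)"],
        )

    def subset(self, indices) -> "SpectralLibrary":
        idx = np.asarray(indices)
        props = self.properties.iloc[idx].reset_index(drop=True)
        keep = set(props["sample_id"])
        dup = {k: v for k, v in self.duplicate_lab.items() if k in keep}
        return SpectralLibrary(props, self.wavelengths, self.scans[idx], dup)
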