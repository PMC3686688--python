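"""Spectral pre-treatments: from raw duplicate scans to the model matrix.

The chain mirrors standard Vis-NIR practice for soil spectra: average the
two instrument scans with a between-scan quality check, convert reflectance
to absorbance, correct the detector-splice step at 1100 nm, trim the noisy
400-500 nm region, apply Savitzky-Golay smoothing or first derivative
(window 101 points, 3rd-order polynomial), optionally a Standard Normal
Variate transform, and keep one band in twenty — leaving ~200 predictors.
Continuum removal (upper convex hull normalisation) is provided for
exploratory analysis and sample selection.

Each transform is a scikit-learn style transformer operating on a
:class:`~soilspec.containers.SpectraMatrix` (plain 2-D arrays are accepted
and wrapped on an index grid); all are stateless, so ``fit`` is a no-op and
they compose in ``sklearn.pipeline.Pipeline``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import SpectraMatrix, SpectralLibrary
from .errors import ConstantSpectrumError, SoilSpecError, UnknownRecipeError

#: Named pre-treatment recipes: A = absorbance only, SG0 = smoothing,
#: SG1 = first derivative, optionally followed by SNV.
RECIPES = ("A", "SG0", "SG1", "SG0+SNV", "SG1+SNV")


def _as_matrix(X) -> SpectraMatrix:
    if isinstance(X, SpectraMatrix):
        return X
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return SpectraMatrix(np.arange(X.shape[1], dtype=float), X)


class _SpectraTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer base: fit is a no-op, transform delegates."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return self._transform(_as_matrix(X))


class AbsorbanceTransform(_SpectraTransformer):
    """Reflectance -> absorbance, A = log10(1/R); exactly invertible."""

    def _transform(self, m: SpectraMatrix) -> SpectraMatrix:
        if np.any(m.values <= 0):
            raise SoilSpecError("reflectance must be strictly positive")
        return m.evolve(values=-np.log10(m.values), mode="absorbance",
                        step="reflectance_to_absorbance")

    def inverse_transform(self, X):
        m = _as_matrix(X)
        return m.evolve(values=10.0 ** (-m.values), mode="reflectance",
                        step="absorbance_to_reflectance")


class SpliceCorrector(_SpectraTransformer):
    """Remove the additive absorbance step at the detector splice.

    For each sample an offset is added to all bands >= ``splice_nm`` so that
    the first long-wavelength value equals the local polynomial
    extrapolation of the last short-wavelength values (a quadratic through
    the last three points; linear when only two are available).  Bands below
    the splice are untouched.  The quadratic removes the curvature error a
    two-point linear extrapolation leaves when an absorption-band shoulder
    crosses the splice.
    """

    def __init__(self, splice_nm: float = 1100.0):
        self.splice_nm = splice_nm

    def _transform(self, m: SpectraMatrix) -> SpectraMatrix:
        wl = m.wavelengths
        j = int(np.searchsorted(wl, self.splice_nm))  # first band >= splice
        if j < 2 or j >= wl.size:
            raise SoilSpecError(
                f"splice at {self.splice_nm} nm must lie strictly inside the grid "
                "with >= 2 bands below it"
            )
        k = min(3, j)  # extrapolation stencil
        x = wl[j - k:j] - wl[j]
        V = np.vander(x, k, increasing=True)
        # value of the fitted polynomial at the first long band (x = 0)
        w = np.linalg.solve(V.T, np.eye(k)[0])
        expected = m.values[:, j - k:j] @ w
        offset = expected - m.values[:, j]
        values = m.values.copy()
        values[:, j:] += offset[:, None]
        return m.evolve(values=values,
                        step=f"splice_correct(splice_nm={self.splice_nm})")


class Trimmer(_SpectraTransformer):
    """Drop all bands with wavelength < ``min_nm``."""

    def __init__(self, min_nm: float = 500.0):
        self.min_nm = min_nm

    def _transform(self, m: SpectraMatrix) -> SpectraMatrix:
        keep = m.wavelengths >= self.min_nm
        if not keep.any():
            raise SoilSpecError(f"trim at {self.min_nm} nm removes every band")
        return m.evolve(values=m.values[:, keep], wavelengths=m.wavelengths[keep],
                        step=f"trim(min_nm={self.min_nm})")


class SavitzkyGolayFilter(_SpectraTransformer):
    """Savitzky-Golay local-polynomial smoothing or differentiation.

    ``deriv=1`` returns the first derivative in absorbance per band step
    (the grid step, 0.5 nm by default, is deliberately not divided out; the
    unit is recorded in provenance).  Terminal windows are handled by
    evaluating the edge-window polynomial at off-centre positions, keeping
    the grid length intact.
    """

    def __init__(self, window: int = 101, polyorder: int = 3, deriv: int = 0):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv

    def _transform(self, m: SpectraMatrix) -> SpectraMatrix:
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise SoilSpecError("window must be odd and greater than polyorder")
        if self.deriv not in (0, 1):
            raise SoilSpecError("deriv must be 0 or 1")
        if m.n_bands < self.window:
            raise SoilSpecError(
                f"window {self.window} exceeds band count {m.n_bands}"
            )
        values = savgol_filter(
            m.values, self.window, self.polyorder, deriv=self.deriv,
            delta=1.0, axis=1, mode="interp",
        )
        mode = "sg_first_derivative" if self.deriv else "sg_smoothed"
        return m.evolve(
            values=values, mode=mode,
            step=(f"savitzky_golay(window={self.window}, polyorder={self.polyorder}, "
                  f"deriv={self.deriv}, units=per-band-step)"),
        )


class SNVScaler(_SpectraTransformer):
    """Standard Normal Variate: centre and scale each spectrum by its own
    mean and SD (n-1 denominator)."""

    def _transform(self, m: SpectraMatrix) -> SpectraMatrix:
        sd = m.values.std(axis=1, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ConstantSpectrumError(
                f"constant spectrum, SNV undefined: sample(s) "
                f"{list(m.sample_ids[bad[:5]])}"
            )
        values = (m.values - m.values.mean(axis=1, keepdims=True)) / sd[:, None]
        return m.evolve(values=values, mode="snv", step="snv")


class Decimator(_SpectraTransformer):
    """Keep bands at indices 0, factor, 2*factor, ... of the current grid."""

    def __init__(self, factor: int = 20):
        self.factor = factor

    def _transform(self, m: SpectraMatrix) -> SpectraMatrix:
        if self.factor < 1:
            raise SoilSpecError("factor must be >= 1")
        sl = slice(None, None, self.factor)
        return m.evolve(values=m.values[:, sl], wavelengths=m.wavelengths[sl],
                        step=f"decimate(factor={self.factor})")


def _upper_hull(wl: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Upper convex hull of (wl, y) evaluated at wl, endpoints pinned.

    qhull prunes the candidate set to the hull vertices; a monotone chain
    over those (sorted by wavelength) extracts the upper chain.  Degenerate
    (collinear) spectra fall back to the full point set.
    """
    pts = np.column_stack([wl, y])
    if wl.size >= 3:
        try:
            cand = pts[np.sort(ConvexHull(pts).vertices)]
        except QhullError:  # collinear input: the chain below handles it
            cand = pts
    else:
        cand = pts
    chain: list[np.ndarray] = []
    for p in cand:
        while len(chain) >= 2:
            o, a = chain[-2], chain[-1]
            cross = (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0])
            if cross >= 0:  # non-right turn: a is not an upper-hull vertex
                chain.pop()
            else:
                break
        chain.append(p)
    hx = np.array([p[0] for p in chain])
    hy = np.array([p[1] for p in chain])
    return np.interp(wl, hx, hy)


class ContinuumRemover(_SpectraTransformer):
    """Divide each reflectance spectrum by its upper convex hull, so
    absorption features become depths below 1 and hull points map to 1."""

    def _transform(self, m: SpectraMatrix) -> SpectraMatrix:
        if m.mode != "reflectance":
            raise SoilSpecError(
                f"continuum removal expects reflectance, got {m.mode!r}"
            )
        if m.n_bands < 2:
            raise SoilSpecError("continuum removal needs >= 2 bands")
        values = np.empty_like(m.values)
        for i in range(m.n_samples):
            hull = _upper_hull(m.wavelengths, m.values[i])
            values[i] = m.values[i] / hull
        np.clip(values, None, 1.0, out=values)
        return m.evolve(values=values, mode="continuum_removed",
                        step="continuum_remove")


# --------------------------------------------------------------------------
# Scan averaging with quality control
# --------------------------------------------------------------------------

@dataclass
class QcReport:
    """Between-scan reproducibility check.

    ``mean_sd`` holds, per sample, the per-band SD between scans (n-1
    denominator) averaged over bands; samples above ``threshold`` are
    removed.  Samples with a single scan cannot be checked and pass through
    with a warning.
    """

    mean_sd: pd.Series
    removed: list[str]
    threshold: float
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.mean_sd.index,
            "mean_sd": self.mean_sd.to_numpy(),
            "removed": [s in set(self.removed) for s in self.mean_sd.index],
        })


def average_scans_qc(
    lib: SpectralLibrary, threshold: float | None = 0.01
) -> tuple[SpectraMatrix, QcReport]:
    """Average duplicate scans in absorbance; drop irreproducible samples.

    The QC statistic follows instrument practice: per-band SD between the
    scans of a sample, averaged over wavelengths, compared in absorbance
    units against ``threshold`` (None disables removal).
    """
    absorb = -np.log10(lib.scans)  # (n, n_scans, bands)
    ids = lib.sample_ids
    if lib.n_scans >= 2:
        sd = absorb.std(axis=1, ddof=1).mean(axis=1)
        warnings: list[str] = []
    else:
        sd = np.zeros(lib.n_samples)
        warnings = [f"{s}: single scan, QC not applicable" for s in ids]
    mean_sd = pd.Series(sd, index=ids, name="mean_sd")

    thr = np.inf if threshold is None else threshold
    removed_mask = mean_sd.to_numpy() > thr
    removed = list(ids[removed_mask])
    keep = ~removed_mask

    mean_abs = absorb.mean(axis=1)[keep]
    matrix = SpectraMatrix(
        wavelengths=lib.wavelengths,
        values=10.0 ** (-mean_abs),
        mode="reflectance",
        sample_ids=ids[keep],
        provenance=[f"average_scans_qc(n_scans={lib.n_scans}, threshold={threshold})"],
    )
    return matrix, QcReport(mean_sd, removed, thr, warnings)


# --------------------------------------------------------------------------
# Recipe chain
# --------------------------------------------------------------------------

def recipe_steps(recipe: str, sg_window: int = 101, sg_polyorder: int = 3
                 ) -> list[_SpectraTransformer]:
    """The transformer sequence a named recipe applies after absorbance
    conversion, splice correction and trimming."""
    if recipe not in RECIPES:
        raise UnknownRecipeError(f"unknown recipe {recipe!r}; expected {RECIPES}")
    steps: list[_SpectraTransformer] = []
    if recipe.startswith("SG0"):
        steps.append(SavitzkyGolayFilter(sg_window, sg_polyorder, deriv=0))
    elif recipe.startswith("SG1"):
        steps.append(SavitzkyGolayFilter(sg_window, sg_polyorder, deriv=1))
    if recipe.endswith("+SNV"):
        steps.append(SNVScaler())
    return steps


def build_design_matrix(
    lib: SpectralLibrary,
    recipe: str = "SG1",
    qc_threshold: float | None = 0.01,
    splice_nm: float = 1100.0,
    trim_nm: float = 500.0,
    decimation: int = 20,
    sg_window: int = 101,
    sg_polyorder: int = 3,
) -> tuple[SpectraMatrix, QcReport]:
    """Full pre-treatment chain: scans -> ~200-band model matrix.

    Order: scan averaging + QC -> absorbance -> splice correction ->
    trim -> recipe transforms (SG / SNV) -> 1-in-``decimation`` band
    selection.  On the default 4200-band grid this yields 200 predictors.
    """
    matrix, qc = average_scans_qc(lib, qc_threshold)
    matrix = AbsorbanceTransform().transform(matrix)
    matrix = SpliceCorrector(splice_nm).transform(matrix)
    matrix = Trimmer(trim_nm).transform(matrix)
    for step in recipe_steps(recipe, sg_window, sg_polyorder):
        matrix = step.transform(matrix)
    matrix = Decimator(decimation).transform(matrix)
    return matrix, qc


# thin functional wrappers over the transformers -----------------------------

def reflectance_to_absorbance(m) -> SpectraMatrix:
    return AbsorbanceTransform().transform(m)


def absorbance_to_reflectance(m) -> SpectraMatrix:
    return AbsorbanceTransform().inverse_transform(m)


def splice_correct(m, splice_nm: float = 1100.0) -> SpectraMatrix:
    return SpliceCorrector(splice_nm).transform(m)


def trim(m, min_nm: float = 500.0) -> SpectraMatrix:
    return Trimmer(min_nm).transform(m)


def savitzky_golay(m, window: int = 101, polyorder: int = 3, deriv: int = 0
                   ) -> SpectraMatrix:
    return SavitzkyGolayFilter(window, polyorder, deriv).transform(m)


def snv(m) -> SpectraMatrix:
    return SNVScaler().transform(m)


def decimate(m, factor: int = 20) -> SpectraMatrix:
    return Decimator(factor).transform(m)


def continuum_remove(m) -> SpectraMatrix:
    return ContinuumRemover().transform(m)
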