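"""Pre-treatment chain: each transform against closed forms and brute-force
oracles, plus the full design-matrix contract."""

import numpy as np
import pytest

from soilspec import (
    average_scans_qc,
    build_design_matrix,
    continuum_remove,
    decimate,
    generate_library,
    reflectance_to_absorbance,
    savitzky_golay,
    snv,
    splice_correct,
    trim,
)
from soilspec.containers import SpectraMatrix, SpectralLibrary, default_grid
from soilspec.errors import ConstantSpectrumError, SoilSpecError, UnknownRecipeError
from soilspec.preprocess import AbsorbanceTransform, recipe_steps

from conftest import noise_free_catalog


def _mat(values, wavelengths=None, mode="reflectance"):
    values = np.atleast_2d(np.asarray(values, float))
    wl = np.arange(values.shape[1], dtype=float) if wavelengths is None \
        else np.asarray(wavelengths, float)
    return SpectraMatrix(wl, values, mode=mode)


class TestAbsorbance:
    def test_known_values(self):
        m = _mat([[1.0, 0.1, 0.01]])
        a = reflectance_to_absorbance(m)
        assert np.allclose(a.values, [[0.0, 1.0, 2.0]], atol=1e-12)
        assert a.mode == "absorbance"

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        m = _mat(rng.uniform(0.05, 1.0, (6, 50)))
        back = AbsorbanceTransform().inverse_transform(reflectance_to_absorbance(m))
        assert np.max(np.abs(back.values - m.values)) < 1e-12

    def test_nonpositive_rejected(self):
        with pytest.raises(SoilSpecError):
            reflectance_to_absorbance(_mat([[0.5, 0.0, 0.2]]))


def _library_from_scans(scans, wavelengths):
    """Minimal library wrapper for raw scan arrays."""
    import pandas as pd
    n = scans.shape[0]
    props = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "land_cover": "cropland", "material": "mineral",
        "soc": 10.0, "nitrogen": 1.0, "clay": 20.0, "silt": 40.0,
        "sand": 40.0, "caco3": 0.0, "ph": 6.0, "cec": 10.0,
    })
    return SpectralLibrary(props, wavelengths, scans)


class TestAverageScansQc:
    wl = np.arange(400.0, 500.0, 0.5)

    def test_identical_scans_retained(self):
        r = np.full((1, 2, self.wl.size), 0.5)
        lib = _library_from_scans(r, self.wl)
        matrix, qc = average_scans_qc(lib, threshold=0.01)
        assert qc.removed == []
        assert float(qc.mean_sd.iloc[0]) == 0.0
        assert np.allclose(matrix.values, 0.5)

    def test_constant_offset_removed(self):
        # absorbance scans x and x+0.03: per-band SD = 0.03/sqrt(2) = 0.0212
        a = np.full(self.wl.size, 0.4)
        scans = 10.0 ** (-np.stack([a, a + 0.03]))[None, :, :]
        lib = _library_from_scans(scans, self.wl)
        _, qc = average_scans_qc(lib, threshold=0.01)
        assert qc.mean_sd.iloc[0] == pytest.approx(0.03 / np.sqrt(2), abs=1e-10)
        assert len(qc.removed) == 1

    def test_threshold_none_keeps_everything(self):
        rng = np.random.default_rng(1)
        scans = np.clip(rng.uniform(0.2, 0.8, (5, 2, self.wl.size)), 1e-6, 1)
        lib = _library_from_scans(scans, self.wl)
        matrix, qc = average_scans_qc(lib, threshold=None)
        assert qc.removed == []
        assert matrix.n_samples == 5

    def test_single_scan_flagged_not_dropped(self):
        scans = np.full((2, 1, self.wl.size), 0.5)
        lib = _library_from_scans(scans, self.wl)
        matrix, qc = average_scans_qc(lib, threshold=0.01)
        assert matrix.n_samples == 2
        assert len(qc.warnings) == 2


class TestSpliceCorrect:
    def test_locally_linear_spectrum_unchanged(self):
        wl = np.arange(1000.0, 1200.0, 0.5)
        y = 0.001 * wl + 0.1
        m = _mat([y], wl, mode="absorbance")
        out = splice_correct(m, 1100.0)
        assert np.max(np.abs(out.values - m.values)) < 1e-12

    def test_step_on_linear_spectrum_removed_exactly(self):
        wl = np.arange(1000.0, 1200.0, 0.5)
        y = 0.002 * wl + 0.05 + np.where(wl >= 1100.0, 0.02, 0.0)
        out = splice_correct(_mat([y], wl, mode="absorbance"), 1100.0)
        assert np.max(np.abs(out.values[0] - (0.002 * wl + 0.05))) < 1e-12

    def test_recovers_injected_offset_on_synthetic_library(self):
        cat = noise_free_catalog(splice_offset=0.05)
        ref = noise_free_catalog(splice_offset=0.0)
        lib = generate_library(3, "mineral", seed=9, catalog=cat)
        lib_ref = generate_library(3, "mineral", seed=9, catalog=ref)
        a = splice_correct(reflectance_to_absorbance(lib.reflectance()))
        b = reflectance_to_absorbance(lib_ref.reflectance())
        # identical up to the (smooth) band structure: offset removed exactly
        assert np.max(np.abs(a.values - b.values)) < 1e-9

    def test_boundary_splice_rejected(self):
        wl = np.arange(1000.0, 1100.0, 0.5)
        with pytest.raises(SoilSpecError):
            splice_correct(_mat([wl * 0.001], wl, mode="absorbance"), 1000.0)


class TestTrim:
    @pytest.mark.parametrize("min_nm, expected", [(500.0, 4000), (2000.0, 1000)])
    def test_band_counts_on_default_grid(self, min_nm, expected, grid):
        m = _mat(np.ones((2, grid.size)), grid)
        assert trim(m, min_nm).n_bands == expected

    def test_trim_at_first_band_is_identity(self, grid):
        m = _mat(np.ones((1, grid.size)), grid)
        assert trim(m, 400.0).n_bands == grid.size

    def test_empty_result_rejected(self, grid):
        with pytest.raises(SoilSpecError):
            trim(_mat(np.ones((1, grid.size)), grid), 3000.0)


def _sg_oracle(y, window, polyorder, deriv):
    """Direct per-window least-squares polynomial fit, with edge windows
    evaluated at off-centre positions."""
    n = y.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = min(max(i - half, 0), n - window)
        idx = np.arange(lo, lo + window)
        coeffs = np.polynomial.polynomial.polyfit(idx - i, y[idx], polyorder)
        out[i] = coeffs[deriv] * (1 if deriv == 0 else 1)  # derivative at x=0
    return out


class TestSavitzkyGolay:
    def test_cubic_polynomial_reproduced(self):
        x = np.arange(300, dtype=float)
        y = 2.0 - 0.01 * x + 3e-4 * x**2 - 1e-6 * x**3
        out = savitzky_golay(_mat([y], x, mode="absorbance"), 101, 3, 0)
        interior = slice(50, -50)
        assert np.max(np.abs(out.values[0, interior] - y[interior])) < 1e-9

    def test_linear_spectrum_first_derivative_constant(self):
        x = np.arange(300, dtype=float)
        y = 0.25 + 0.003 * x
        out = savitzky_golay(_mat([y], x, mode="absorbance"), 101, 3, 1)
        assert np.allclose(out.values, 0.003, atol=1e-10)

    @pytest.mark.parametrize("deriv", [0, 1])
    def test_matches_local_least_squares_oracle(self, deriv):
        rng = np.random.default_rng(5)
        y = rng.normal(size=60)
        out = savitzky_golay(_mat([y], mode="absorbance"), 5, 2, deriv)
        expected = _sg_oracle(y, 5, 2, deriv)
        assert np.max(np.abs(out.values[0] - expected)) < 1e-10

    def test_window_larger_than_grid_rejected(self):
        with pytest.raises(SoilSpecError):
            savitzky_golay(_mat(np.ones((1, 50)), mode="absorbance"), 101, 3, 0)

    def test_even_window_rejected(self):
        with pytest.raises(SoilSpecError):
            savitzky_golay(_mat(np.ones((1, 300)), mode="absorbance"), 100, 3, 0)


class TestSnv:
    def test_three_point_row(self):
        out = snv(_mat([[1.0, 2.0, 3.0]], mode="absorbance"))
        assert np.allclose(out.values, [[-1.0, 0.0, 1.0]], atol=1e-12)

    def test_rows_standardized(self):
        rng = np.random.default_rng(2)
        out = snv(_mat(rng.normal(size=(8, 40)), mode="absorbance"))
        assert np.max(np.abs(out.values.mean(axis=1))) < 1e-12
        assert np.max(np.abs(out.values.std(axis=1, ddof=1) - 1)) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = _mat(rng.normal(size=(4, 30)), mode="absorbance")
        once = snv(m)
        twice = snv(once)
        assert np.max(np.abs(twice.values - once.values)) < 1e-12

    def test_constant_spectrum_rejected_with_sample_named(self):
        m = SpectraMatrix(np.arange(5.0), np.vstack([np.ones(5), np.arange(5.0)]),
                          mode="absorbance", sample_ids=np.array(["flat", "ok"]))
        with pytest.raises(ConstantSpectrumError, match="flat"):
            snv(m)


class TestDecimate:
    @pytest.mark.parametrize("n_bands, factor, expected",
                             [(4000, 20, 200), (4001, 20, 201), (10, 1, 10)])
    def test_band_counts(self, n_bands, factor, expected):
        m = _mat(np.ones((1, n_bands)), mode="absorbance")
        assert decimate(m, factor).n_bands == expected

    def test_keeps_anchored_grid(self):
        wl = np.arange(500.0, 600.0, 0.5)
        out = decimate(_mat(np.ones((1, wl.size)), wl, mode="absorbance"), 20)
        assert out.wavelengths[0] == 500.0
        assert np.allclose(np.diff(out.wavelengths), 10.0)


def _cr_oracle(wl, y):
    """O(n^2) continuum: hull height at band i is the max over all chords
    (j, k) with j <= i <= k of the chord evaluated at wl[i]."""
    n = wl.size
    hull = y.copy()
    for j in range(n):
        for k in range(j + 1, n):
            inside = slice(j, k + 1)
            chord = y[j] + (y[k] - y[j]) * (wl[inside] - wl[j]) / (wl[k] - wl[j])
            hull[inside] = np.maximum(hull[inside], chord)
    return y / hull


class TestContinuumRemoval:
    def test_linear_spectrum_all_ones(self):
        wl = np.linspace(400, 2500, 50)
        y = 0.2 + 1e-4 * (wl - 400)
        out = continuum_remove(_mat([y], wl))
        assert np.allclose(out.values, 1.0, atol=1e-12)

    def test_three_band_hand_geometry(self):
        out = continuum_remove(_mat([[0.5, 0.2, 0.6]], [500.0, 1000.0, 1500.0]))
        assert np.allclose(out.values[0], [1.0, 0.2 / 0.55, 1.0], atol=1e-12)

    def test_matches_chord_oracle_on_random_spectra(self):
        rng = np.random.default_rng(7)
        wl = np.sort(rng.uniform(400, 2500, 40))
        for _ in range(10):
            y = rng.uniform(0.1, 0.9, wl.size)
            ours = continuum_remove(_mat([y], wl)).values[0]
            assert np.max(np.abs(ours - _cr_oracle(wl, y))) < 1e-10

    def test_endpoints_pinned_to_one(self, small_mineral_library):
        out = continuum_remove(small_mineral_library.reflectance())
        assert np.allclose(out.values[:, 0], 1.0, atol=1e-12)
        assert np.allclose(out.values[:, -1], 1.0, atol=1e-12)
        assert (out.values > 0).all() and (out.values <= 1).all()

    def test_non_reflectance_rejected(self):
        with pytest.raises(SoilSpecError):
            continuum_remove(_mat(np.ones((1, 5)), mode="absorbance"))


class TestBuildDesignMatrix:
    def test_sg1_shape_and_provenance(self, small_mineral_library):
        m, qc = build_design_matrix(small_mineral_library, "SG1")
        assert m.values.shape == (40 - len(qc.removed), 200)
        assert len(m.provenance) == 6
        assert m.mode == "sg_first_derivative"

    def test_recipe_a_has_no_sg_snv_steps(self, small_mineral_library):
        m, _ = build_design_matrix(small_mineral_library, "A")
        joined = " ".join(m.provenance)
        assert "savitzky" not in joined and "snv" not in joined
        assert m.mode == "absorbance"

    def test_snv_recipes_standardize_before_decimation(self, small_mineral_library):
        # the SNV stage output is exactly standardized; the decimated
        # subsample keeps that only approximately
        steps = recipe_steps("SG1+SNV")
        assert type(steps[-1]).__name__ == "SNVScaler"
        m, _ = build_design_matrix(small_mineral_library, "SG1+SNV")
        assert np.max(np.abs(m.values.mean(axis=1))) < 0.2
        assert m.mode == "snv"

    def test_unknown_recipe_rejected(self, small_mineral_library):
        with pytest.raises(UnknownRecipeError):
            build_design_matrix(small_mineral_library, "MSC")

    def test_sample_order_preserved(self, small_mineral_library):
        m, qc = build_design_matrix(small_mineral_library, "SG0")
        kept = [s for s in small_mineral_library.sample_ids
                if s not in set(qc.removed)]
        assert list(m.sample_ids) == kept

    def test_deterministic_bit_identical(self, small_mineral_library):
        a, _ = build_design_matrix(small_mineral_library, "SG1")
        b, _ = build_design_matrix(small_mineral_library, "SG1")
        assert np.array_equal(a.values, b.values)
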