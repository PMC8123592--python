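"""Savitzky-Golay filtering, scatter corrections, and ROI extraction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemospec import synthetic_data as sd
from hemospec.grid import WavelengthGrid
from hemospec.hypercube_io import Hypercube
from hemospec.preprocess import (
    SGSpec,
    crop_roi,
    extract_roi,
    msc,
    sg_coefficients,
    sg_filter,
    snv,
)


def brute_force_sg(x: np.ndarray, spec: SGSpec, spacing: float) -> np.ndarray:
    """Independent oracle: per-point sliding least-squares polynomial fit,
    with the edge points evaluated from the first/last window's fit."""
    n = x.size
    half = spec.window // 2
    out = np.empty(n)
    positions = np.arange(spec.window) - half
    from math import factorial

    for i in range(n):
        c = min(max(i, half), n - 1 - half)  # window centre (clamped at edges)
        window = x[c - half : c + half + 1]
        coeffs = np.polynomial.polynomial.polyfit(positions, window, spec.polyorder)
        offset = i - c  # evaluate derivative at the true point, not the centre
        val = 0.0
        for p in range(spec.deriv, spec.polyorder + 1):
            val += (
                coeffs[p]
                * factorial(p)
                / factorial(p - spec.deriv)
                * offset ** (p - spec.deriv)
            )
        out[i] = val / spacing**spec.deriv
    return out


def test_classical_smoothing_kernel():
    w = sg_coefficients(SGSpec(5, 2, 0))
    np.testing.assert_allclose(w, np.array([-3, 12, 17, 12, -3]) / 35, atol=1e-12)


@pytest.mark.parametrize("spec", [SGSpec(13, 3, 0), SGSpec(7, 4, 0), SGSpec(5, 2, 0)])
def test_smoothing_weights_preserve_constants(spec):
    assert sg_coefficients(spec).sum() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("spec", [SGSpec(13, 3, 2), SGSpec(9, 4, 2)])
def test_second_derivative_weights_annihilate_lines(spec):
    w = sg_coefficients(spec)
    pos = np.arange(spec.window) - spec.window // 2
    assert w.sum() == pytest.approx(0.0, abs=1e-10)
    assert (w * pos).sum() == pytest.approx(0.0, abs=1e-10)


def test_sgspec_validation():
    with pytest.raises(ValueError):
        SGSpec(12, 3, 2)  # even window
    with pytest.raises(ValueError):
        SGSpec(13, 13, 2)  # polyorder >= window
    with pytest.raises(ValueError):
        SGSpec(13, 3, 4)  # deriv > polyorder


def test_cubic_polynomial_reproduced_exactly():
    x = np.linspace(0, 1, 50)
    y = 1.0 - 2.0 * x + 3.0 * x**2 - 0.5 * x**3
    out = sg_filter(y, SGSpec(13, 3, 0), spacing=x[1] - x[0])
    np.testing.assert_allclose(out, y, atol=1e-10)


def test_quadratic_second_derivative_is_constant():
    a = 0.7
    t = np.arange(40.0)
    out = sg_filter(a * t**2, SGSpec(13, 3, 2), spacing=1.0)
    np.testing.assert_allclose(out, 2 * a, atol=1e-9)


@pytest.mark.parametrize("spec", [SGSpec(13, 3, 2), SGSpec(13, 3, 0), SGSpec(7, 2, 1)])
def test_sg_filter_matches_sliding_least_squares(rng, spec):
    x = rng.standard_normal(64)
    spacing = 2.7
    got = sg_filter(x, spec, spacing=spacing)
    want = brute_force_sg(x, spec, spacing)
    np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)


def test_sg_filter_rejects_short_input():
    with pytest.raises(ValueError, match="shorter than window"):
        sg_filter(np.zeros(10), SGSpec(13, 3, 2))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(alpha=st.floats(-5, 5, allow_nan=False), beta=st.floats(-5, 5, allow_nan=False))
def test_sg_filter_linearity(alpha, beta):
    rng = np.random.default_rng(7)
    x, y = rng.standard_normal((2, 40))
    spec = SGSpec(13, 3, 2)
    lhs = sg_filter(alpha * x + beta * y, spec)
    rhs = alpha * sg_filter(x, spec) + beta * sg_filter(y, spec)
    np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)


def test_snv_properties(rng):
    x = rng.random((6, 30)) + 0.5
    z = snv(x)
    np.testing.assert_allclose(z.mean(axis=-1), 0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=-1), 1, atol=1e-12)
    np.testing.assert_allclose(snv(3.0 * x + 0.2), z, atol=1e-9)
    with pytest.raises(ValueError, match="constant"):
        snv(np.full(20, 0.3))


def test_msc_recovers_reference(rng):
    ref = rng.random(25) + 0.5
    spectra = np.vstack([ref, 2.0 * ref + 0.1])
    out = msc(spectra, reference=ref)
    np.testing.assert_allclose(out[0], ref, atol=1e-10)
    np.testing.assert_allclose(out[1], ref, atol=1e-10)


def test_msc_matches_normal_equations(rng):
    spectra = rng.random((5, 30)) + 0.2
    ref = spectra.mean(axis=0)
    out = msc(spectra)
    for row, corrected in zip(spectra, out):
        # independent per-spectrum normal-equations solve
        A = np.column_stack([np.ones_like(ref), ref])
        a, b = np.linalg.solve(A.T @ A, A.T @ row)
        np.testing.assert_allclose(corrected, (row - a) / b, rtol=1e-9)


def test_roi_mask_matches_truth_without_noise(grid):
    stains = [
        sd.StainPlacement(sd.blood_spec(), 1, (20.0, 20.0), 12.0),
        sd.StainPlacement(sd.substance_library()[2], 2, (50.0, 55.0), 14.0),
    ]
    design = sd.SceneDesign("white_tile", 1, stains, (70, 80, len(grid)))
    cube, truth = sd.render_scene(design, noise=sd.ZERO_NOISE, seed=0, grid=grid)
    mask = extract_roi(cube)
    assert mask.n_stains == 2
    np.testing.assert_array_equal(mask.mask, truth > 0)


def test_roi_on_uniform_background_is_empty(grid):
    design = sd.SceneDesign("white_tile", 1, [], (50, 50, len(grid)))
    cube, _ = sd.render_scene(design, seed=1, grid=grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = extract_roi(cube)
    assert mask.is_empty


def test_roi_crop_convention(grid):
    design = sd.SceneDesign(
        "white_tile",
        1,
        [sd.StainPlacement(sd.blood_spec(), 1, (80.0, 90.0), 14.0)],
        (160, 180, len(grid)),
    )
    cube, _ = sd.render_scene(design, seed=0, grid=grid)
    crop = crop_roi(cube, center=(80, 90), size=100)
    assert crop.shape == (100, 100, 224)


def test_roi_wavelength_out_of_range(grid):
    cube = Hypercube(np.ones((5, 5, len(grid)), np.float32), grid)
    with pytest.raises(ValueError, match="outside grid"):
        extract_roi(cube, wavelength_nm=2000)


def test_blood_derivative_curvature_brackets_dips(grid):
    """The deriv-2 spectrum shows the alpha/beta dips as positive curvature
    extrema with sign changes on both flanks."""
    r = sd.blood_reflectance(grid, day=1, donor_seed=1, substrate="white_tile")
    d2 = sg_filter(r, SGSpec(13, 3, 2), spacing=grid.spacing)
    for nm in (540.0, 577.0):
        i = grid.index_of(nm)
        assert d2[i] > 0
        below = d2[grid.window(nm - 30, nm - 2)]
        above = d2[grid.window(nm + 2, nm + 30)]
        assert (below < 0).any(), f"no sign change below {nm}"
        assert (above < 0).any(), f"no sign change above {nm}"


def test_derivative_homogenizes_aged_spectra(grid):
    """Day-1 vs day-3 mean blood spectra are closer in standardized
    second-derivative space (470-770 nm) than in raw reflectance."""
    rng = np.random.default_rng(0)
    blood = sd.blood_spec()
    noise = sd.NoiseParams()
    win = grid.window(470, 770)

    def pixels(day):
        model = blood.reflectance(grid, day=day, substrate="white_tile")
        return sd._noisy_pixels(model, 300, noise, rng)

    def standardized_distance(A, B):
        pooled_sd = np.vstack([A, B]).std(axis=0)
        pooled_sd[pooled_sd == 0] = 1.0
        return float(np.linalg.norm((A.mean(0) - B.mean(0)) / pooled_sd))

    raw1, raw3 = pixels(1), pixels(3)
    spec = SGSpec(13, 3, 2)
    d1 = sg_filter(raw1, spec, spacing=grid.spacing)
    d3 = sg_filter(raw3, spec, spacing=grid.spacing)
    assert standardized_distance(d1[:, win], d3[:, win]) < standardized_distance(
        raw1[:, win], raw3[:, win]
    )
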