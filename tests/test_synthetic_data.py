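"""Spectral and structural properties of the synthetic data generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemospec import synthetic_data as sd
from hemospec.grid import WavelengthGrid
from hemospec.preprocess import SGSpec, sg_filter


def test_library_composition(library, grid):
    assert len(library) == 9
    bloods = [s for s in library if s.is_blood]
    assert len(bloods) == 1 and bloods[0].name == "blood"
    troughs = [s for s in library if not s.is_blood and s.nir_trough is not None]
    assert len(troughs) >= 2
    for t in troughs:
        assert 920 <= t.nir_trough.center <= 930
    # every confuser is red-hued: strong absorption below ~600 nm
    base = sd.substrate_baseline("white_tile", grid)
    win = grid.window(450, 600)
    for spec in library:
        r = spec.reflectance(grid, substrate="white_tile")
        assert r[win].mean() < 0.5 * base[win].mean(), spec.name


def test_blood_alpha_beta_minima_on_grid(grid):
    r = sd.blood_reflectance(grid, day=1, donor_seed=7, substrate="white_tile")
    for nm in (540.0, 577.0):
        i = grid.index_of(nm)
        assert r[i] < r[i - 1] and r[i] < r[i + 1], f"no local minimum at {nm} nm"


def test_rust_paint_reflectance_hump(library, grid):
    rust = next(s for s in library if s.name == "rust_acrylic_paint")
    r = rust.reflectance(grid, substrate="white_tile")
    win = grid.window(500, 520)
    i = win[np.argmax(r[win])]
    assert r[i] > r[i - 1] and r[i] > r[i + 1], "no local maximum within 500-520 nm"


@pytest.mark.parametrize("substrate", sd.SUBSTRATES)
def test_aging_flattens_dips_and_slope(grid, substrate):
    blood = sd.blood_spec()
    depths_a, depths_b, slopes = [], [], []
    win = grid.window(600, 650)
    for day in sd.DAYS:
        r = blood.reflectance(grid, day=day, substrate=substrate)
        depths_a.append(sd.dip_depth(r, grid, 577, (560, 600)))
        depths_b.append(sd.dip_depth(r, grid, 540, (520, 560)))
        ls_slope = np.polyfit(grid.centers[win], r[win], 1)[0]
        # closed-form oracle: dR/dlambda of the generating model
        analytic = (-np.log(10) * blood.absorbance_derivative(grid.centers[win], day)
                    * r[win]).mean()
        assert ls_slope > 0
        assert ls_slope == pytest.approx(analytic, rel=0.15)
        slopes.append(ls_slope)
    assert depths_a[0] > depths_a[1] > depths_a[2]
    assert depths_b[0] > depths_b[1] > depths_b[2]
    assert slopes[0] > slopes[1] > slopes[2]


def test_blood_reflectance_determinism_and_validation(grid):
    a = sd.blood_reflectance(grid, day=2, donor_seed=3, substrate="wall_sheet")
    b = sd.blood_reflectance(grid, day=2, donor_seed=3, substrate="wall_sheet")
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError, match="day"):
        sd.blood_reflectance(grid, day=4, donor_seed=3, substrate="wall_sheet")


def test_fabric_is_more_absorbing_than_other_substrates(grid):
    fabric = sd.substrate_baseline("white_fabric", grid)
    for other in ("white_tile", "wall_sheet"):
        assert np.all(fabric < sd.substrate_baseline(other, grid))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    day=st.sampled_from(sd.DAYS),
    donor_seed=st.integers(0, 2**31 - 1),
    substrate=st.sampled_from(sd.SUBSTRATES),
)
def test_reflectance_bounds_property(day, donor_seed, substrate):
    grid = WavelengthGrid.default()
    for spec in sd.substance_library():
        scale = sd.donor_scale_from_seed(donor_seed) if spec.is_blood else 1.0
        r = spec.reflectance(grid, day=day, substrate=substrate, donor_scale=scale)
        assert np.all(np.isfinite(r))
        assert np.all(r > 0) and np.all(r <= 1.2)


def _single_stain_design(grid, diameter=12.0, day=1):
    placement = sd.StainPlacement(sd.blood_spec(), 5, (30.0, 30.0), diameter, day=day)
    return sd.SceneDesign("white_tile", day, [placement], (60, 60, len(grid)))


def test_render_scene_zero_noise_degeneracy(grid):
    design = _single_stain_design(grid)
    cube, labels = sd.render_scene(design, noise=sd.ZERO_NOISE, seed=0, grid=grid)
    px = cube.data[labels == 1]
    assert px.shape[0] == np.sum(sd._disc_mask((60, 60), (30.0, 30.0), 12.0))
    np.testing.assert_array_equal(px, np.tile(px[0], (px.shape[0], 1)))


def test_render_scene_rejects_overlap(grid):
    stains = [
        sd.StainPlacement(sd.blood_spec(), 1, (30.0, 30.0), 14.0),
        sd.StainPlacement(sd.blood_spec(), 2, (34.0, 34.0), 14.0),
    ]
    design = sd.SceneDesign("white_tile", 1, stains, (60, 60, len(grid)))
    with pytest.raises(ValueError, match="overlap"):
        sd.render_scene(design, seed=0, grid=grid)


def test_render_scene_mean_matches_model_over_seeds(grid):
    design = _single_stain_design(grid)
    model = sd.blood_spec().reflectance(
        grid, day=1, substrate="white_tile", donor_scale=sd.donor_scale_from_seed(5)
    )
    means = []
    for seed in range(20):
        cube, labels = sd.render_scene(design, seed=seed, grid=grid)
        means.append(cube.data[labels == 1].mean(axis=0))
    grand = np.mean(means, axis=0)
    # per-pixel noise ~1-3%; 20 seeds x ~110 px shrink the SE far below 1%
    assert np.max(np.abs(grand - model)) < 0.01


def test_full_design_counts(small_design):
    records = [r for ds in small_design for r in ds.records]
    assert len(records) == 225
    assert sum(r.class_label == "blood" for r in records) == 81
    assert sum(r.class_label == "non_blood" for r in records) == 144
    for ds in small_design:
        assert sum(r.class_label == "blood" for r in ds.records) == 9
        assert sum(r.class_label == "non_blood" for r in ds.records) == 16
    counts = {r.n_pixels for r in records}
    assert len(counts) > 10, "per-stain pixel counts should vary"


def test_full_design_determinism():
    a = sd.generate_full_design(seed=5, diameter_range=(8.0, 10.0), days=(1,))
    b = sd.generate_full_design(seed=5, diameter_range=(8.0, 10.0), days=(1,))
    for ds_a, ds_b in zip(a, b):
        for ra, rb in zip(ds_a.records, ds_b.records):
            assert ra.stain_id == rb.stain_id
            np.testing.assert_array_equal(ra.spectra, rb.spectra)


def test_blind_scene_composition(grid):
    excluded = sd.design_donor_seeds(9)
    scene = sd.generate_blind_scene(
        "white_tile", 9, exclude_donor_seeds=excluded, shape=(140, 200)
    )
    assert scene.cube.shape == (140, 200, 224)
    classes = [s["class_label"] for s in scene.stains]
    assert classes.count("blood") == 2 and classes.count("non_blood") == 4
    assert scene.donor_seed not in set(int(s) for s in excluded)
    days = [s["day"] for s in scene.stains if s["class_label"] == "blood"]
    assert days[0] != days[1], "the two blind bloodstains carry different aging"
    # truth labels partition all stain pixels
    ids = np.unique(scene.labels)
    assert set(ids) == set(range(0, 7))
    blood_rows = [np.mean(np.where(scene.labels == k)[0]) for k in (1, 2)]
    assert all(r < 140 * 0.3 for r in blood_rows), "bloodstains sit in the top region"


def test_default_blind_scene_shape_constant():
    assert sd.BLIND_SCENE_SHAPE == (410, 512)


def test_second_derivative_discriminability(grid):
    """Mean second-derivative spectra of blood vs each confuser separate by
    more than 5 pooled noise SDs somewhere in 470-770 nm (noise on)."""
    rng = np.random.default_rng(1)
    noise = sd.NoiseParams()
    spec_sg = SGSpec(13, 3, 2)
    win = grid.window(470, 770)

    def deriv_pixels(spec):
        model = spec.reflectance(grid, day=1, substrate="white_tile")
        px = sd._noisy_pixels(model, 200, noise, rng)
        return sg_filter(px, spec_sg, spacing=grid.spacing)[:, win]

    blood = deriv_pixels(sd.blood_spec())
    for conf in (s for s in sd.substance_library() if not s.is_blood):
        other = deriv_pixels(conf)
        pooled_sd = np.sqrt((blood.var(axis=0) + other.var(axis=0)) / 2)
        sep = np.abs(blood.mean(axis=0) - other.mean(axis=0)) / pooled_sd
        assert sep.max() > 5.0, conf.name
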