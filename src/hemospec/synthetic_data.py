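"""Synthetic VNIR hypercubes of bloodstains and red confuser substances.

Real captures of dried bloodstains are rarely shareable, so this module
generates labelled hypercubes whose spectra carry the physics the
identification criteria rest on:

* blood reflectance with the oxyhemoglobin beta/alpha dips at 540/577 nm,
  the Soret band near 415 nm, and the steep 600-650 nm rise produced by
  hemichrome/methemoglobin formation in dried blood;
* dip flattening and slope decay as stains age over three days;
* donor-to-donor baseline level shifts with fixed band positions;
* eight red-hued confusers (ketchup, paints, nail polishes, fake blood,
  red ink) that mimic blood in raw reflectance but lack its sharp band
  structure, including the rust-paint reflectance hump near 510 nm and
  faint 920-930 nm troughs on some substances;
* three substrates (absorbing white cotton fabric, white tile, PVC wall
  sheet) and pixel-level noise (additive heteroscedastic, per-pixel
  multiplicative gain and baseline offset).

Reflectance follows a Beer-Lambert style multiplicative model

    R(lambda) = donor_scale * baseline * B_substrate(lambda) * 10**(-A(lambda))

with absorbance A a sum of Gaussian bands plus a smooth logistic shelf
that produces the 600-650 nm slope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .grid import WavelengthGrid

SUBSTRATES = ("white_fabric", "white_tile", "wall_sheet")
DAYS = (1, 2, 3)

# Aging multipliers, days 1..3: labile band depths (alpha/beta and the broad
# heme shelf) and the hemichrome slope term. Direction is physical (dips and
# slope decay as hemoglobin denatures); magnitudes are model defaults.
AGING_BAND_SCALE = (1.0, 0.7, 0.45)
AGING_SLOPE_SCALE = (1.0, 0.8, 0.6)

# Half-width (nm) and centre (nm) of the logistic absorbance shelf that
# realises slope_600_650; the shelf decays smoothly through 600-650 nm.
_SLOPE_SHELF_WIDTH = 80.0
_SLOPE_SHELF_CENTER = 625.0
_SLOPE_SHELF_TAU = 20.0

DONOR_BASELINE_SPAN = 0.10  # +-10% donor baseline level scaling


@dataclass(frozen=True)
class GaussianBand:
    """One absorbance band: Gaussian in wavelength, depth in absorbance units.

    ``labile`` bands flatten as the stain ages (hemoglobin alpha/beta and the
    broad heme shelf); non-labile bands (Soret, met-Hb, pigment bands) do not.
    """

    center: float
    width: float
    depth: float
    labile: bool = False

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.depth < 0:
            raise ValueError("band depth must be non-negative")


@dataclass(frozen=True)
class SubstanceSpec:
    """Parametric absorption model defining one substance's reflectance."""

    name: str
    is_blood: bool
    bands: tuple[GaussianBand, ...]
    baseline_reflectance: float = 1.0
    slope_600_650: float = 0.0  # absorbance per nm carried by the shelf
    nir_trough: GaussianBand | None = None
    ages: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.baseline_reflectance <= 1.0:
            raise ValueError("baseline_reflectance must lie in (0, 1]")

    # -- spectral model -------------------------------------------------

    def absorbance(self, wavelengths: np.ndarray, day: int = 1) -> np.ndarray:
        band_scale, slope_scale = _aging_scales(day, self.ages)
        lam = np.asarray(wavelengths, dtype=float)
        a = np.zeros_like(lam)
        for b in self.bands:
            depth = b.depth * (band_scale if b.labile else 1.0)
            a += depth * np.exp(-0.5 * ((lam - b.center) / b.width) ** 2)
        if self.nir_trough is not None:
            t = self.nir_trough
            a += t.depth * np.exp(-0.5 * ((lam - t.center) / t.width) ** 2)
        if self.slope_600_650:
            s = self.slope_600_650 * slope_scale
            a += s * _SLOPE_SHELF_WIDTH * expit(
                (_SLOPE_SHELF_CENTER - lam) / _SLOPE_SHELF_TAU
            )
        return a

    def absorbance_derivative(self, wavelengths: np.ndarray, day: int = 1) -> np.ndarray:
        """Closed-form dA/dlambda of the generating model (oracle for slope tests)."""
        band_scale, slope_scale = _aging_scales(day, self.ages)
        lam = np.asarray(wavelengths, dtype=float)
        da = np.zeros_like(lam)
        for b in self.bands:
            depth = b.depth * (band_scale if b.labile else 1.0)
            g = np.exp(-0.5 * ((lam - b.center) / b.width) ** 2)
            da += depth * g * (-(lam - b.center) / b.width**2)
        if self.nir_trough is not None:
            t = self.nir_trough
            g = np.exp(-0.5 * ((lam - t.center) / t.width) ** 2)
            da += t.depth * g * (-(lam - t.center) / t.width**2)
        if self.slope_600_650:
            s = self.slope_600_650 * slope_scale
            z = expit((_SLOPE_SHELF_CENTER - lam) / _SLOPE_SHELF_TAU)
            da += -s * _SLOPE_SHELF_WIDTH / _SLOPE_SHELF_TAU * z * (1 - z)
        return da

    def reflectance(
        self,
        grid: WavelengthGrid,
        day: int = 1,
        substrate: str = "white_tile",
        donor_scale: float = 1.0,
    ) -> np.ndarray:
        if day not in DAYS:
            raise ValueError(f"day must be one of {DAYS}, got {day!r}")
        base = substrate_baseline(substrate, grid)
        r = (
            donor_scale
            * self.baseline_reflectance
            * base
            * 10.0 ** (-self.absorbance(grid.centers, day))
        )
        return r


def _aging_scales(day: int, ages: bool) -> tuple[float, float]:
    if day not in DAYS:
        raise ValueError(f"day must be one of {DAYS}, got {day!r}")
    if not ages:
        return 1.0, 1.0
    return AGING_BAND_SCALE[day - 1], AGING_SLOPE_SCALE[day - 1]


def substrate_baseline(substrate: str, grid: WavelengthGrid) -> np.ndarray:
    """Smooth substrate reflectance. Cotton fabric is markedly absorbing."""
    lam = grid.centers
    x = (lam - 700.0) / 300.0
    if substrate == "white_tile":
        return 0.92 - 0.01 * x**2
    if substrate == "wall_sheet":
        return 0.85 + 0.02 * x - 0.015 * x**2
    if substrate == "white_fabric":
        # cellulose absorbs: lower overall level, mild curvature
        return 0.58 + 0.04 * x - 0.03 * x**2
    raise ValueError(f"unknown substrate {substrate!r}; choose from {SUBSTRATES}")


def donor_scale_from_seed(donor_seed: int, span: float = DONOR_BASELINE_SPAN) -> float:
    """Per-donor baseline level multiplier in [1 - span, 1 + span]."""
    rng = np.random.default_rng(int(donor_seed))
    return float(1.0 + span * rng.uniform(-1.0, 1.0))


def blood_reflectance(
    grid: WavelengthGrid, day: int, donor_seed: int, substrate: str
) -> np.ndarray:
    """Noise-free blood reflectance spectrum for one donor/day/substrate."""
    return blood_spec().reflectance(
        grid, day=day, substrate=substrate, donor_scale=donor_scale_from_seed(donor_seed)
    )


# ---------------------------------------------------------------------------
# substance library


def blood_spec() -> SubstanceSpec:
    return SubstanceSpec(
        name="blood",
        is_blood=True,
        bands=(
            GaussianBand(415.0, 20.0, 1.2),            # Soret
            GaussianBand(540.0, 12.0, 0.45, labile=True),  # beta
            GaussianBand(577.0, 10.0, 0.40, labile=True),  # alpha
            GaussianBand(555.0, 55.0, 0.35, labile=True),  # broad heme shelf
            GaussianBand(630.0, 40.0, 0.15),           # met-Hb
        ),
        baseline_reflectance=1.0,
        slope_600_650=0.004,
        nir_trough=GaussianBand(925.0, 20.0, 0.05),
        ages=True,
    )


def substance_library() -> list[SubstanceSpec]:
    """Blood plus the eight red confusers (9 specs, exactly one blood).

    All confusers absorb strongly below ~600 nm (red hue) so their raw
    reflectance resembles blood; their bands are broad, so their second
    derivatives are flat where blood's alpha/beta curvature peaks. Rust
    acrylic paint carries two bands whose gap makes a reflectance hump near
    510 nm; fake blood and red ink carry faint troughs near 925 nm.
    """
    return [
        blood_spec(),
        SubstanceSpec(
            name="ketchup",
            is_blood=False,
            bands=(GaussianBand(515.0, 60.0, 0.85),),
            baseline_reflectance=0.90,
            slope_600_650=0.0012,
        ),
        SubstanceSpec(
            name="rust_acrylic_paint",
            is_blood=False,
            bands=(GaussianBand(465.0, 28.0, 0.90), GaussianBand(560.0, 38.0, 0.85)),
            baseline_reflectance=0.88,
        ),
        SubstanceSpec(
            name="red_acrylic_paint",
            is_blood=False,
            bands=(GaussianBand(535.0, 70.0, 1.0),),
            baseline_reflectance=0.92,
        ),
        SubstanceSpec(
            name="brown_acrylic_paint",
            is_blood=False,
            bands=(GaussianBand(520.0, 80.0, 0.70), GaussianBand(700.0, 120.0, 0.25)),
            baseline_reflectance=0.80,
        ),
        SubstanceSpec(
            name="red_nail_polish",
            is_blood=False,
            bands=(GaussianBand(528.0, 52.0, 0.95),),
            baseline_reflectance=0.95,
        ),
        SubstanceSpec(
            name="rust_nail_polish",
            is_blood=False,
            bands=(GaussianBand(485.0, 45.0, 0.80), GaussianBand(585.0, 55.0, 0.55)),
            baseline_reflectance=0.85,
        ),
        SubstanceSpec(
            name="fake_blood",
            is_blood=False,
            bands=(GaussianBand(548.0, 65.0, 0.90),),
            baseline_reflectance=0.88,
            slope_600_650=0.0018,
            nir_trough=GaussianBand(925.0, 18.0, 0.05),
        ),
        SubstanceSpec(
            name="red_ink",
            is_blood=False,
            bands=(GaussianBand(522.0, 48.0, 1.1),),
            baseline_reflectance=0.93,
            nir_trough=GaussianBand(928.0, 15.0, 0.04),
        ),
    ]


def dip_depth(
    spectrum: np.ndarray,
    grid: WavelengthGrid,
    center_nm: float,
    flanks_nm: tuple[float, float],
) -> float:
    """Continuum-removed relative dip depth: 1 - R(center)/R_continuum(center).

    The continuum is the straight line between the two flank wavelengths;
    this is the standard band-depth measure and is insensitive to the
    overall brightening that accompanies dip flattening.
    """
    i = grid.index_of(center_nm)
    lo, hi = (grid.index_of(f) for f in flanks_nm)
    lam = grid.centers
    frac = (lam[i] - lam[lo]) / (lam[hi] - lam[lo])
    continuum = spectrum[lo] + frac * (spectrum[hi] - spectrum[lo])
    return float(1.0 - spectrum[i] / continuum)


# ---------------------------------------------------------------------------
# noise model and scene rendering


@dataclass(frozen=True)
class NoiseParams:
    """Pixel-level noise: eps ~ N(0, (additive_sd*(0.25+R))^2) per band,
    gain m ~ N(1, multiplicative_sd^2) and offset b ~ N(0, baseline_sd^2)
    per pixel; pixel spectrum = m*R + b + eps."""

    additive_sd: float = 0.01
    multiplicative_sd: float = 0.03
    baseline_sd: float = 0.01

    def scaled(self, factor: float) -> "NoiseParams":
        return NoiseParams(
            self.additive_sd * factor,
            self.multiplicative_sd * factor,
            self.baseline_sd * factor,
        )


ZERO_NOISE = NoiseParams(0.0, 0.0, 0.0)


def _noisy_pixels(
    model: np.ndarray, n_pixels: int, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    m = 1.0 + noise.multiplicative_sd * rng.standard_normal((n_pixels, 1))
    b = noise.baseline_sd * rng.standard_normal((n_pixels, 1))
    eps = rng.standard_normal((n_pixels, model.size)) * (
        noise.additive_sd * (0.25 + model)[None, :]
    )
    return (m * model[None, :] + b + eps).astype(np.float32)


@dataclass(frozen=True)
class StainPlacement:
    spec: SubstanceSpec
    entity_id: int  # donor seed for blood, substance index otherwise
    center: tuple[float, float]  # (row, col) in pixels
    diameter: float  # pixels; ~1 cm stains at the emulated resolution
    day: int = 1


@dataclass
class SceneDesign:
    substrate: str
    day: int
    stains: list[StainPlacement]
    cube_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"unknown substrate {self.substrate!r}")
        rows, cols, _ = self.cube_shape
        for s in self.stains:
            r, c = s.center
            rad = s.diameter / 2.0
            if r - rad < 0 or r + rad > rows or c - rad < 0 or c + rad > cols:
                raise ValueError(f"stain at {s.center} exceeds cube bounds")


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], diameter: float):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = center
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= (diameter / 2.0) ** 2


def render_scene(
    design: SceneDesign,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    grid: WavelengthGrid | None = None,
):
    """Render a scene to a reflectance cube and a ground-truth label image.

    Returns ``(cube, labels)`` where ``cube`` is a
    :class:`~hemospec.hypercube_io.Hypercube` and ``labels`` an int image,
    0 = background, k = the k-th stain of ``design.stains``.
    Overlapping stain footprints are an error.
    """
    from .hypercube_io import Hypercube  # local import to avoid a cycle

    grid = grid or WavelengthGrid.default()
    rows, cols, bands = design.cube_shape
    if bands != len(grid):
        raise ValueError("cube_shape band count does not match grid")
    rng = np.random.default_rng(seed)

    base = substrate_baseline(design.substrate, grid).astype(np.float64)
    model = np.broadcast_to(base, (rows, cols, bands)).copy()
    labels = np.zeros((rows, cols), dtype=np.int32)

    for k, stain in enumerate(design.stains, start=1):
        mask = _disc_mask((rows, cols), stain.center, stain.diameter)
        if np.any(labels[mask] != 0):
            raise ValueError(f"stain {k} overlaps a previously placed stain")
        donor_scale = (
            donor_scale_from_seed(stain.entity_id) if stain.spec.is_blood else 1.0
        )
        spectrum = stain.spec.reflectance(
            grid, day=stain.day, substrate=design.substrate, donor_scale=donor_scale
        )
        model[mask] = spectrum
        labels[mask] = k

    m = 1.0 + noise.multiplicative_sd * rng.standard_normal((rows, cols, 1))
    b = noise.baseline_sd * rng.standard_normal((rows, cols, 1))
    eps = rng.standard_normal((rows, cols, bands)).astype(np.float32) * (
        noise.additive_sd * (0.25 + model)
    )
    data = (model * m + b + eps).astype(np.float32)
    cube = Hypercube(
        data=data,
        grid=grid,
        metadata={"substrate": design.substrate, "day": design.day, "seed": seed},
    )
    return cube, labels


# ---------------------------------------------------------------------------
# labelled datasets (pixel spectra per stain)


@dataclass
class StainRecord:
    """All pixel spectra of one stain plus its labels."""

    stain_id: str
    class_label: str  # "blood" | "non_blood"
    substance: str
    donor: int | None
    day: int
    substrate: str
    spectra: np.ndarray  # (n_pixels, n_bands) float32

    @property
    def n_pixels(self) -> int:
        return self.spectra.shape[0]


@dataclass
class LabeledDataset:
    records: list[StainRecord]
    substrate: str
    day: int
    seed: int
    grid: WavelengthGrid

    def pixel_matrix(self):
        """Stack all pixels; returns (X, labels DataFrame)."""
        import pandas as pd

        X = np.vstack([r.spectra for r in self.records])
        rows = []
        for r in self.records:
            rows.extend(
                {
                    "stain_id": r.stain_id,
                    "class_label": r.class_label,
                    "substance": r.substance,
                    "donor": r.donor,
                    "day": r.day,
                    "substrate": r.substrate,
                }
                for _ in range(r.n_pixels)
            )
        return X, pd.DataFrame(rows)


def combine_datasets(datasets: Sequence[LabeledDataset]):
    """Stack several datasets into one (X, labels DataFrame) pair."""
    import pandas as pd

    parts = [ds.pixel_matrix() for ds in datasets]
    X = np.vstack([p[0] for p in parts])
    df = pd.concat([p[1] for p in parts], ignore_index=True)
    return X, df


N_DONORS = 3
N_BLOOD_REPLICATES = 3
N_CONFUSER_REPLICATES = 2
DEFAULT_DIAMETER_RANGE = (14.0, 18.0)  # px; disc area ~200 px, varying


def design_donor_seeds(seed: int, n_donors: int = N_DONORS) -> np.ndarray:
    """The donor seeds used by :func:`generate_full_design` for a master seed."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n_donors)


def _stain_pixel_count(diameter: float, rng: np.random.Generator) -> int:
    # subpixel disc centre so equal diameters still give varying footprints
    r0, c0 = rng.uniform(0.0, 1.0, size=2)
    rad = diameter / 2.0
    n = int(np.ceil(diameter)) + 2
    rr, cc = np.mgrid[0:n, 0:n]
    return int(np.sum((rr - rad - r0) ** 2 + (cc - rad - c0) ** 2 <= rad**2))


def generate_full_design(
    seed: int,
    grid: WavelengthGrid | None = None,
    noise: NoiseParams = NoiseParams(),
    diameter_range: tuple[float, float] = DEFAULT_DIAMETER_RANGE,
    substrates: Sequence[str] = SUBSTRATES,
    days: Sequence[int] = DAYS,
    donor_span: float = DONOR_BASELINE_SPAN,
) -> list[LabeledDataset]:
    """Generate the full experimental design.

    For each substrate x day: 9 blood stains (3 donors x 3 replicates) and
    16 non-blood stains (8 substances x 2 replicates) -- with the default
    3 substrates x 3 days this totals 225 stain cubes, 81 blood and 144
    non-blood. Each stain's pixel spectra are drawn for a disc footprint of
    sampled diameter, so pixel counts vary stain to stain.
    """
    grid = grid or WavelengthGrid.default()
    donor_seeds = design_donor_seeds(seed)
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(substrates) * len(days))
    library = substance_library()
    confusers = [s for s in library if not s.is_blood]
    blood = next(s for s in library if s.is_blood)

    datasets: list[LabeledDataset] = []
    idx = 0
    for substrate in substrates:
        for day in days:
            rng = np.random.default_rng(children[idx])
            idx += 1
            records: list[StainRecord] = []
            for donor_idx, donor_seed in enumerate(donor_seeds, start=1):
                scale = donor_scale_from_seed(int(donor_seed), span=donor_span)
                spectrum = blood.reflectance(
                    grid, day=day, substrate=substrate, donor_scale=scale
                )
                for rep in range(1, N_BLOOD_REPLICATES + 1):
                    d = rng.uniform(*diameter_range)
                    n_pix = _stain_pixel_count(d, rng)
                    records.append(
                        StainRecord(
                            stain_id=f"{substrate}-d{day}-blood{donor_idx}-r{rep}",
                            class_label="blood",
                            substance="blood",
                            donor=donor_idx,
                            day=day,
                            substrate=substrate,
                            spectra=_noisy_pixels(spectrum, n_pix, noise, rng),
                        )
                    )
            for conf in confusers:
                spectrum = conf.reflectance(grid, day=day, substrate=substrate)
                for rep in range(1, N_CONFUSER_REPLICATES + 1):
                    d = rng.uniform(*diameter_range)
                    n_pix = _stain_pixel_count(d, rng)
                    records.append(
                        StainRecord(
                            stain_id=f"{substrate}-d{day}-{conf.name}-r{rep}",
                            class_label="non_blood",
                            substance=conf.name,
                            donor=None,
                            day=day,
                            substrate=substrate,
                            spectra=_noisy_pixels(spectrum, n_pix, noise, rng),
                        )
                    )
            datasets.append(
                LabeledDataset(
                    records=records, substrate=substrate, day=day, seed=seed, grid=grid
                )
            )
    return datasets


@dataclass
class BlindScene:
    """A blind-trial scene: cube + truth labels + per-stain info."""

    cube: "object"  # Hypercube
    labels: np.ndarray
    stains: list[dict]  # per stain id (1-based): class/substance/day/donor_seed
    donor_seed: int


BLIND_SCENE_SHAPE = (410, 512)


def generate_blind_scene(
    substrate: str,
    seed: int,
    exclude_donor_seeds: Iterable[int] = (),
    grid: WavelengthGrid | None = None,
    noise: NoiseParams = NoiseParams(),
    shape: tuple[int, int] = BLIND_SCENE_SHAPE,
) -> BlindScene:
    """A blind-trial scene: two bloodstains of a new donor (different aging)
    in the top row region, four confuser stains below."""
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB11AD]))
    exclude = set(int(s) for s in exclude_donor_seeds)
    donor_seed = int(rng.integers(0, 2**31 - 1))
    while donor_seed in exclude:
        donor_seed = int(rng.integers(0, 2**31 - 1))

    rows, cols = shape
    confusers = [s for s in substance_library() if not s.is_blood]
    picks = rng.choice(len(confusers), size=4, replace=False)
    blood = blood_spec()
    blood_days = rng.choice(DAYS, size=2, replace=False)

    col_slots = np.linspace(cols * 0.15, cols * 0.85, 4)
    stains = [
        StainPlacement(
            blood, donor_seed, (rows * 0.15, float(col_slots[i + 1])), 20.0,
            day=int(blood_days[i]),
        )
        for i in range(2)
    ]
    day = int(rng.choice(DAYS))
    for j, p in enumerate(picks):
        r = rows * (0.45 if j < 2 else 0.75)
        c = float(col_slots[j % 2 * 2 + (0 if j < 2 else 1)])
        stains.append(
            StainPlacement(confusers[p], int(p), (r, c), float(rng.uniform(16, 24)), day=day)
        )

    design = SceneDesign(
        substrate=substrate, day=day, stains=stains, cube_shape=(rows, cols, len(grid))
    )
    cube, labels = render_scene(design, noise=noise, seed=int(rng.integers(2**31 - 1)), grid=grid)
    info = [
        {
            "stain_id": k,
            "class_label": "blood" if s.spec.is_blood else "non_blood",
            "substance": s.spec.name,
            "day": s.day,
            "donor_seed": donor_seed if s.spec.is_blood else None,
        }
        for k, s in enumerate(stains, start=1)
    ]
    return BlindScene(cube=cube, labels=labels, stains=info, donor_seed=donor_seed)


def write_manifest(datasets: Sequence[LabeledDataset], path) -> None:
    """Write a stain id -> labels manifest table (CSV)."""
    import pandas as pd

    rows = [
        {
            "stain_id": r.stain_id,
            "class_label": r.class_label,
            "substance": r.substance,
            "donor": r.donor,
            "day": r.day,
            "substrate": r.substrate,
            "n_pixels": r.n_pixels,
        }
        for ds in datasets
        for r in ds.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
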