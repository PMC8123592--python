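"""ROI extraction and spectral pre-treatment.

The stain footprint is segmented from the single band nearest 540 nm (the
beta-band wavelength, where bloodstains are darkest against bright
substrates). Spectral pre-treatments are the chemometric standards: SNV,
MSC, and Savitzky-Golay filtering -- in particular the second derivative
with a 13-point window and third-order polynomial, which turns the subtle
alpha/beta dips into large curvature features and removes baseline and
donor/aging level shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_coeffs, savgol_filter
from skimage.filters import threshold_otsu

from .grid import WavelengthGrid
from .hypercube_io import Hypercube

ROI_WAVELENGTH_NM = 540.0


@dataclass(frozen=True)
class SGSpec:
    """Savitzky-Golay filter settings: window points, polynomial order,
    derivative order (0 = smoothing, 2 = the curvature features used for
    classification)."""

    window: int = 13
    polyorder: int = 3
    deriv: int = 2

    def __post_init__(self) -> None:
        if self.window % 2 != 1 or self.window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if not 0 <= self.polyorder < self.window:
            raise ValueError("polyorder must satisfy 0 <= polyorder < window")
        if not 0 <= self.deriv <= self.polyorder:
            raise ValueError("deriv must satisfy 0 <= deriv <= polyorder")


def sg_coefficients(spec: SGSpec, spacing: float = 1.0) -> np.ndarray:
    """Centre-evaluation weights of the local least-squares polynomial.

    ``w @ x[window]`` equals the ``deriv``-th derivative, at the window
    centre, of the least-squares polynomial of order ``polyorder`` through
    the window samples, in units of signal * spacing**(-deriv).
    """
    return savgol_coeffs(
        spec.window, spec.polyorder, deriv=spec.deriv, delta=spacing, use="dot"
    )


def sg_filter(x: np.ndarray, spec: SGSpec, spacing: float = 1.0) -> np.ndarray:
    """Apply the Savitzky-Golay filter along the last axis.

    Interior points are the kernel convolution; at the edges the polynomial
    is refit on the first/last window and evaluated there, so the output has
    the input's length. Linear in its input.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < spec.window:
        raise ValueError(
            f"spectrum length {x.shape[-1]} shorter than window {spec.window}"
        )
    return savgol_filter(
        x, spec.window, spec.polyorder, deriv=spec.deriv, delta=spacing,
        axis=-1, mode="interp",
    )


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd along last axis."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)):
        raise ValueError("SNV undefined for a constant spectrum (zero SD)")
    return (x - mean) / sd


def msc(spectra: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction.

    Each spectrum is regressed onto the reference (default: the mean
    spectrum), x ~ a + b*ref, and returned as (x - a) / b.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[0] < 2 and reference is None:
        raise ValueError("MSC needs at least two spectra (or an explicit reference)")
    ref = spectra.mean(axis=0) if reference is None else np.asarray(reference, float)
    design = np.column_stack([np.ones_like(ref), ref])
    coef, *_ = np.linalg.lstsq(design, spectra.T, rcond=None)
    a, b = coef  # each (n_spectra,)
    if np.any(np.abs(b) < 1e-12):
        idx = np.flatnonzero(np.abs(b) < 1e-12)
        raise ValueError(f"MSC slope ~ 0 for spectra at rows {idx.tolist()}")
    return (spectra - a[:, None]) / b[:, None]


# ---------------------------------------------------------------------------
# ROI extraction


@dataclass
class StainMask:
    """Connected-component stain mask: 0 = background, k = stain k."""

    labels: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_stains(self) -> int:
        return int(self.labels.max())

    def component(self, k: int) -> np.ndarray:
        return self.labels == k

    @property
    def is_empty(self) -> bool:
        return self.n_stains == 0


def extract_roi(
    cube: Hypercube,
    wavelength_nm: float = ROI_WAVELENGTH_NM,
    method: str = "otsu",
    threshold: float | None = None,
    min_area: int = 20,
    stain_is_dark: bool = True,
    separation_sd: float = 4.0,
) -> StainMask:
    """Segment stain footprints from the band image nearest ``wavelength_nm``.

    Default thresholding is Otsu on that single band; stains are the
    low-reflectance side on bright substrates. If the two threshold classes
    are separated by less than ``separation_sd`` pooled standard deviations
    the image is treated as stainless (empty mask, with a warning) -- Otsu
    always splits, even pure background noise.
    """
    lo, hi = cube.grid.centers[0], cube.grid.centers[-1]
    if not lo <= wavelength_nm <= hi:
        raise ValueError(f"wavelength {wavelength_nm} nm outside grid [{lo}, {hi}]")
    img = cube.band_image(wavelength_nm)
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        t = threshold
    elif method == "otsu":
        if np.ptp(img) == 0:
            return StainMask(np.zeros(img.shape, dtype=np.int32))
        t = threshold_otsu(img)
        # on near-discrete histograms the Otsu bin centre can land inside a
        # cluster; a few intermeans iterations settle it into the gap
        for _ in range(5):
            low_px, high_px = img[img <= t], img[img > t]
            if not low_px.size or not high_px.size:
                break
            t_new = (low_px.mean() + high_px.mean()) / 2.0
            if t_new == t:
                break
            t = t_new
        low, high = img[img < t], img[img >= t]
        pooled = np.sqrt((low.var() + high.var()) / 2.0) or 1e-12
        if (high.mean() - low.mean()) < separation_sd * pooled:
            warnings.warn("no stain-background separation at the ROI band; empty mask")
            return StainMask(np.zeros(img.shape, dtype=np.int32))
    else:
        raise ValueError(f"unknown ROI method {method!r}")
    mask = img < t if stain_is_dark else img > t
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_area) + 1
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, keep.size + 1)
        labels = relabel[labels]
    if labels.max() == 0:
        warnings.warn("ROI extraction found no stain components; empty mask")
    return StainMask(labels.astype(np.int32))


def crop_roi(cube: Hypercube, center: tuple[int, int], size: int = 100) -> Hypercube:
    """Crop a stain-centred ``size x size`` window (the per-stain cube
    reduction convention), clamped to the cube bounds."""
    rows, cols, _ = cube.shape
    half = size // 2
    r0 = int(np.clip(center[0] - half, 0, max(rows - size, 0)))
    c0 = int(np.clip(center[1] - half, 0, max(cols - size, 0)))
    data = cube.data[r0 : r0 + size, c0 : c0 + size]
    meta = dict(cube.metadata, crop_origin=(r0, c0))
    return Hypercube(data=data, grid=cube.grid, metadata=meta)
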