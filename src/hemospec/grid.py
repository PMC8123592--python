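"""Wavelength grid of the pushbroom VNIR camera.

The instrument emulated throughout the package samples 224 bands uniformly
over 397-1003 nm (mean spacing ~2.7 nm). Every hypercube, spectrum and
feature table carries (or assumes) one of these grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_BANDS = 224
DEFAULT_RANGE_NM = (397.0, 1003.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band centers in nanometres."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1 or centers.size < 2:
            raise ValueError("grid needs at least two band centers")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        object.__setattr__(self, "centers", centers)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        lo, hi = DEFAULT_RANGE_NM
        return cls(np.linspace(lo, hi, DEFAULT_N_BANDS))

    def __len__(self) -> int:
        return self.centers.size

    @property
    def spacing(self) -> float:
        """Mean band spacing in nm."""
        return float(np.mean(np.diff(self.centers)))

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band center nearest ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.centers - wavelength_nm)))

    def window(self, lower_nm: float, upper_nm: float) -> np.ndarray:
        """Indices of all band centers in the closed interval [lower, upper]."""
        mask = (self.centers >= lower_nm) & (self.centers <= upper_nm)
        return np.flatnonzero(mask)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.centers.shape == other.centers.shape and np.allclose(
            self.centers, other.centers
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.centers.size, float(self.centers[0]), float(self.centers[-1])))
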