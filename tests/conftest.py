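import numpy as np
import pytest

from hemospec import synthetic_data as sd
from hemospec.grid import WavelengthGrid


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def small_design():
    """Full 225-stain design with small stains (~70 px) for fast tests."""
    return sd.generate_full_design(seed=11, diameter_range=(8.0, 11.0))


@pytest.fixture(scope="session")
def library():
    return sd.substance_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
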