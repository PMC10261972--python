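import numpy as np
import pytest

from sphagspec.spectral_io import SampleMeta, SpectralLibrary, WavelengthGrid
from sphagspec.synthetic import SimulationConfig, generate_library


@pytest.fixture(scope="session")
def coarse_grid():
    """Short grid for hand-built fixtures (600–900 nm at 10 nm, 31 bands)."""
    return WavelengthGrid(600, 900, 10)


@pytest.fixture(scope="session")
def default_library():
    """One full-design synthetic library (9 species x 10 reps x 4 times)."""
    return generate_library(SimulationConfig(seed=11))


def make_library(grid, spectra, species, times, sample_ids=None):
    """Assemble a library from parallel lists (test helper)."""
    n = len(spectra)
    sample_ids = sample_ids or [f"s{i:02d}" for i in range(n)]
    meta = [
        SampleMeta(sample_id=sid, species=sp, measurement_time=t)
        for sid, sp, t in zip(sample_ids, species, times)
    ]
    return SpectralLibrary(grid, meta, np.asarray(spectra, dtype=float))
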