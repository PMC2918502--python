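import numpy as np
import pytest

from eggcolor import GeneratorConfig, SampleKey, generate_dataset
from eggcolor.spectra import GRID_NM, GridSpectrum, RawSpectrum


@pytest.fixture
def key():
    return SampleKey("F01", "F01_sp1", "c1", "e1", 1, 1900)


@pytest.fixture
def fine_wl():
    """0.4 nm sampling covering slightly beyond the analysis range."""
    return np.arange(298.0, 702.0 + 1e-9, 0.4)


@pytest.fixture
def constant_raw(fine_wl, key):
    return RawSpectrum(fine_wl, np.full_like(fine_wl, 50.0), key)


def grid_spec(values, key=None):
    return GridSpectrum(reflectance_pct=np.asarray(values, float), meta=key)


@pytest.fixture
def toy_grid(key):
    rng = np.random.default_rng(7)
    return grid_spec(rng.uniform(5.0, 80.0, len(GRID_NM)), key)


@pytest.fixture(scope="session")
def small_dataset():
    """A tiny but fully structured synthetic study (2 families, ... , 3 reps)."""
    return generate_dataset(
        GeneratorConfig(
            n_families=3,
            species_per_family=4,
            clutches_per_species=2,
            eggs_per_clutch=2,
            replicates_per_egg=3,
            seed=123,
        )
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One realization of the default study conditions."""
    return generate_dataset(GeneratorConfig(seed=2024))
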