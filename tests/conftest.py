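import numpy as np
import pytest

from quadcal import (
    KGrid,
    NoiseJitterSpec,
    ReflectorSet,
    get_preset,
    make_kgrid,
    simulate_mirror_measurement,
)


@pytest.fixture(scope="session")
def grid256() -> KGrid:
    return make_kgrid(256)


@pytest.fixture(scope="session")
def grid1024() -> KGrid:
    return make_kgrid(1024)


@pytest.fixture
def quiet() -> NoiseJitterSpec:
    return NoiseJitterSpec(noise_sigma=0.0, jitter=0.0, seed=0)


@pytest.fixture
def ideal_tone(grid1024, quiet):
    """Noiseless ideal-quadrature single-reflector batch on an integer bin."""
    z = 128 * grid1024.zbar_spacing
    batch = simulate_mirror_measurement(
        get_preset("ideal"), ReflectorSet([z], [1.0]), grid1024, quiet, M=1
    )
    return batch, z


def on_bin_depth(grid: KGrid, bins: int) -> float:
    return bins * grid.zbar_spacing


@pytest.fixture(scope="session")
def realistic():
    return get_preset("realistic")
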