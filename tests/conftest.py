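import numpy as np
import pytest

from oecp import (
    BilayerConfig,
    FrequencyGrid,
    G1,
    ideal_probe_coefficients,
    invert_sweep,
    load_material_library,
    synthesize_sweep,
)


@pytest.fixture(scope="session")
def library():
    return load_material_library()


@pytest.fixture(scope="session")
def grid():
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def teflon(library):
    return library["teflon"]


@pytest.fixture(scope="session")
def water(library):
    return library["deionized_water"]


@pytest.fixture
def noise_free_sweep_factory(library, grid):
    """Build a noise-free, inverted bilayer sweep for a given liquid/probe/D_true."""

    def make(material_name="deionized_water", probe=G1, d_true=0.62,
             axis="vertical", max_displacement=2.0):
        config = BilayerConfig(
            tissue1=library["teflon"],
            tissue2=library[material_name],
            probe=probe,
            axis=axis,
            true_sensing_distance=d_true,
            max_displacement=max_displacement,
        )
        coeffs = ideal_probe_coefficients(probe, grid)
        return invert_sweep(synthesize_sweep(config, grid, coeffs), coeffs)

    return make
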