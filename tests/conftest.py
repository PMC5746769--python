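import numpy as np
import pytest

from wlrs import LayerStack, OpticalLayer, default_grid, simulate_spectrum

# Canonical transducer indices: protein/oxide n=1.46, photoresist n=1.40,
# silicon n=4.00, air ambient.
N_SIO2 = 1.46
N_RESIST = 1.40
N_SI = 4.00
N_PROTEIN = 1.45


@pytest.fixture(scope="session")
def grid():
    return default_grid()  # 450-800 nm, 512 points


@pytest.fixture
def bare_si():
    return LayerStack(ambient_index=1.0, layers=(), substrate_index=N_SI)


@pytest.fixture
def sio2_1000():
    """The standard chip: 1000 nm thermal oxide on Si, in air."""
    return LayerStack(
        ambient_index=1.0,
        layers=(OpticalLayer("SiO2", N_SIO2, 1000.0),),
        substrate_index=N_SI,
    )


@pytest.fixture
def chip_with_adlayer():
    """1000 nm SiO2 + 5 nm protein adlayer on Si."""
    return LayerStack(
        ambient_index=1.0,
        layers=(
            OpticalLayer("SiO2", N_SIO2, 1000.0),
            OpticalLayer("adlayer", N_PROTEIN, 5.0),
        ),
        substrate_index=N_SI,
    )


@pytest.fixture
def sio2_1000_spectrum(sio2_1000, grid):
    return simulate_spectrum(sio2_1000, grid)
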