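import warnings

import numpy as np
import pytest

from neurohcs import synthgen
from neurohcs.io import FieldImage

# synthetic rendering emits benign user warnings in edge-case tests
warnings.filterwarnings("ignore", category=UserWarning)

SMALL = (512, 512)
PS = 0.325


@pytest.fixture(scope="session")
def neurite_field():
    """One medium neurite field with spots and mid colocalization."""
    return synthgen.synth_neurite_field(
        total_neurite_length_um=3000, synapse_density_true=0.05,
        coloc_rho=0.5, seed=11, shape=SMALL,
    )


@pytest.fixture(scope="session")
def nuclei_field():
    return synthgen.synth_nuclei_field(
        n_cells=40, dead_fraction=0.2, crowding=0.3, seed=5, shape=SMALL,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def flat_image(value=7.0, shape=(64, 64), pixel_size=PS):
    return FieldImage(np.full(shape, value), "test", pixel_size)
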