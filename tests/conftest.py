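import numpy as np
import pytest

from gelshield.materials import (
    Material,
    composition_from_formula,
    make_pad_material,
    tissue_material,
    water,
)
from gelshield.photon_physics import MaterialPhotonModel


@pytest.fixture(scope="session")
def water_material():
    return water()


@pytest.fixture(scope="session")
def water_model(water_material):
    return MaterialPhotonModel(water_material)


@pytest.fixture(scope="session")
def bi_pad():
    """2-mm-grade alginate pad doped with 10 wt% Bi2O3."""
    return make_pad_material("alginate", "Bi2O3", 0.10)


@pytest.fixture(scope="session")
def bismuth_metal():
    return Material("Bi-metal", 9.78, composition_from_formula({"Bi": 1}))


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)
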