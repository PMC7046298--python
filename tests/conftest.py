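import numpy as np
import pytest

from ratchetabc.energetics import EnergyModel, TemplateSequence
from ratchetabc.kinetics import ParameterSet
from ratchetabc.synthetic_data import random_template


@pytest.fixture(scope="session")
def energy_model() -> EnergyModel:
    return EnergyModel()


@pytest.fixture(scope="session")
def template() -> TemplateSequence:
    return random_template(120, 0.5, seed=11, identifier="fixture-120")


@pytest.fixture(scope="session")
def landscape(template, energy_model):
    return energy_model.landscape(template)


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    return ParameterSet(
        k_cat=30.0, K_D=20.0, k_bind=0.5, dG_t1=-2.0, delta1=2.5, dG_tdag=5.5
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
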