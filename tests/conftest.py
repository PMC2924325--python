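import pytest

from ribosnitch import EnergyModel, design_switch


@pytest.fixture(scope="session")
def model():
    return EnergyModel.default()


@pytest.fixture(scope="session")
def zero_model(model):
    """Uniform-ensemble variant: every admissible structure has weight 1."""
    return model.zero_energy_variant()


@pytest.fixture(scope="session")
def switch(model):
    """The certified two-state switch construct (seed 0)."""
    return design_switch(seed=0, model=model)
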