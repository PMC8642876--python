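import dataclasses

import pytest

from perioecon import load_parameter_set


@pytest.fixture(scope="session")
def basecase():
    """The shipped base-case parameter set."""
    return load_parameter_set()


@pytest.fixture(scope="session")
def base_inputs(basecase):
    """Flat engine inputs of the base case (5% discount, 30 cycles)."""
    return basecase.to_model_inputs()


@pytest.fixture(scope="session")
def base_inputs_r0(base_inputs):
    """Base case with discounting switched off."""
    return dataclasses.replace(base_inputs, discount_rate=0.0)
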