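import numpy as np
import pytest

from simepet.frames import make_frame_schedule
from simepet.kinetics import model_tac
from simepet.simulate import reference_truth, synth_input


@pytest.fixture(scope="session")
def mmr_schedule():
    return make_frame_schedule("mmr_90")


@pytest.fixture(scope="session")
def input_fn():
    """Default synthetic input covering the 90-min schedule."""
    return synth_input(t_end_min=95.0)


@pytest.fixture(scope="session")
def truth():
    """Six-region truth: common V_ND = 2.35 with distinct regional V_T."""
    return reference_truth()


@pytest.fixture(scope="session")
def clean_tacs(truth, input_fn, mmr_schedule):
    """Noiseless forward-modelled TACs for the six reference regions."""
    return [
        model_tac(rates, input_fn, mmr_schedule, region=name)
        for name, rates in truth.items()
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20230112)
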