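import numpy as np
import pytest

from pkpet.cohort import (
    PhantomSpec,
    class_frame_tacs,
    default_class_kinetics,
    make_class_templates,
    make_phantom,
)
from pkpet.kinetics import (
    FrameSchedule,
    InputFunctionParams,
    TissueKineticParams,
    fine_time_grid,
    plasma_input,
    two_tissue_tac,
    whole_blood,
)


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def input_params():
    return InputFunctionParams()


@pytest.fixture(scope="session")
def t_fine(schedule):
    return fine_time_grid(schedule)


@pytest.fixture(scope="session")
def cp_fine(input_params, t_fine):
    return plasma_input(input_params, t_fine)


@pytest.fixture(scope="session")
def cb_fine(input_params, t_fine):
    return whole_blood(input_params, t_fine)


@pytest.fixture(scope="session")
def templates(input_params, schedule):
    return make_class_templates(input_params, schedule=schedule)


@pytest.fixture(scope="session")
def class_tacs(input_params, schedule):
    """Raw (unnormalized) noiseless frame TACs of the four kinetic classes."""
    return class_frame_tacs(input_params, default_class_kinetics(), schedule)


@pytest.fixture(scope="session")
def noiseless_phantom(input_params, schedule):
    return make_phantom(PhantomSpec(alpha=0.0, seed=1), input_params, schedule)


@pytest.fixture(scope="session")
def noisy_phantom(input_params, schedule):
    return make_phantom(PhantomSpec(alpha=0.3, seed=2), input_params, schedule)


@pytest.fixture(scope="session")
def ref_tissue_fine(cp_fine, cb_fine):
    """Fine-grid one-tissue curve of the reference class without blood share."""
    return two_tissue_tac(cp_fine, TissueKineticParams(K1=0.10, k2t=0.20, vb=0.0), cb=cb_fine)
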