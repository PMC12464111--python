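import numpy as np
import pandas as pd
import pytest

from wagerhgf import build_default_schedule, generate_trial_inputs, simulate_session
from wagerhgf.perceptual import PerceptualParams, SourceParams
from wagerhgf.response import ResponseParams


@pytest.fixture(scope="session")
def schedule():
    return build_default_schedule()


@pytest.fixture(scope="session")
def trial_inputs(schedule):
    return generate_trial_inputs(schedule, 7)


@pytest.fixture(scope="session")
def default_agent():
    pp = PerceptualParams(
        social=SourceParams(kappa=0.46, theta=0.3),
        nonsocial=SourceParams(kappa=0.62, theta=0.3),
    )
    rp = ResponseParams(zeta=1.3, beta=2.0, psi0=0.0, psi1=1.5, psi_vol=3.0, sigma_w=1.5)
    return pp, rp


@pytest.fixture(scope="session")
def session_table(schedule, trial_inputs, default_agent):
    pp, rp = default_agent
    return simulate_session(schedule, pp, rp, 11, trial_inputs=trial_inputs)


@pytest.fixture(scope="session")
def binary_sequence():
    rng = np.random.default_rng(5)
    return (rng.random(20) < 0.7).astype(float)
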