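import numpy as np
import pytest

from wcst_attend import (
    ModelSpec,
    PerceptualParams,
    ResponseParams,
    model_by_name,
    task,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def moderate_params():
    """A well-behaved structured-model parameter point: moderate attractor,
    high subjective process noise (the regime of a switch-aware subject)."""
    perc = PerceptualParams(
        error_rate=0.25, tau_e=0.75, tau_f=0.75, kappa_e=0.5, kappa_f=0.5,
        q_e=1.0, q_f=1.0, w_dist=0.5, mu_e0=0.0, mu_f0=0.0,
        sigma_e0=1.0, sigma_f0=1.0,
    )
    resp = ResponseParams(theta1=1.0, theta2=0.05)
    return perc, resp


@pytest.fixture
def switch_block(rng):
    return task.generate_block(task.switch_condition(), rng)


@pytest.fixture
def simulated_block(rng, moderate_params, switch_block):
    perc, resp = moderate_params
    model = model_by_name("B_w1^r")
    return task.simulate_agent(switch_block, model, perc, resp, rng), model
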