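import math

import pytest

import chemomwc as cm
from chemomwc.synth import campaign_specs, ground_truth


@pytest.fixture(scope="session")
def params():
    return cm.reference_receptor_params()


@pytest.fixture(scope="session")
def wt1_spec():
    """Headline adaptation model at the WT1 adapted activity."""
    return cm.get_model("power-h3", a=1.0 / 3.0)


@pytest.fixture(scope="session")
def a_wt1():
    return 1.0 / 3.0


def _campaign_truths(strain):
    cache, out = {}, []
    for s in campaign_specs(strain):
        if s.protocol not in cache:
            cache[s.protocol] = ground_truth(strain, s.protocol)
        out.append(cache[s.protocol])
    return out


@pytest.fixture(scope="session")
def wt1_truths():
    """Noise-free WT1 campaign simulations, shared across tests."""
    return _campaign_truths("WT1")


@pytest.fixture(scope="session")
def wt2_truths():
    return _campaign_truths("WT2")


@pytest.fixture(scope="session")
def perfect_step_courses(params, wt1_spec, a_wt1):
    """Noiseless perfect-step time courses at 0.1 mM ambient, all step sizes."""
    out = {}
    for delta in (0.03, 0.05, 0.1, 0.4, 2.0):
        proto = cm.StepProtocol.add_remove(
            0.1, delta, 50.0, 650.0, math.inf, math.inf, 800.0
        )
        out[delta] = cm.simulate(proto, params, wt1_spec, a_wt1, dt_sample=0.2)
    return out
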