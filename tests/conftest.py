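import numpy as np
import pytest

from ratrisk.cohort import (
    AgentSpec,
    PRPersistence,
    RDTPolicy,
    StaircaseObserverParams,
)
from ratrisk.rl import RLParams


def _make_agent(
    subject_id="S000",
    age_group="young",
    kappa=1.2,
    beta_rdt=2.5,
    omission_prob=0.0,
    alpha=0.4,
    beta=3.0,
    base_rate=30.0,
    hazard=0.1,
    mu=150.0,
    sigma=20.0,
    locomotor=9.7,
    latency_scale=1.0,
    seed=123,
):
    return AgentSpec(
        subject_id=subject_id,
        age_group=age_group,
        rdt=RDTPolicy(kappa, beta_rdt, omission_prob),
        rl=RLParams(alpha, beta),
        pr=PRPersistence(base_rate, hazard),
        staircase=StaircaseObserverParams(mu, sigma),
        locomotor_rate=locomotor,
        latency_scale=latency_scale,
        seed=seed,
    )


@pytest.fixture
def make_agent():
    """Factory for hand-configured synthetic subjects."""
    return _make_agent


@pytest.fixture
def agent():
    return _make_agent()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
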