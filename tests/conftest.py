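import warnings

import numpy as np
import pytest

from pskstab import (
    HierarchicalTruth,
    Mechanism,
    PassagingProtocol,
    PSKParams,
    generate_loss_curves,
)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def ta_params():
    return PSKParams(lambda_loss=0.01, gamma=0.9, omega=0.95, mechanism=Mechanism.TA)


@pytest.fixture(scope="session")
def short_protocol():
    return PassagingProtocol(n_passages=10)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Nine noisy replicates over 37 passages from a known TA hierarchy."""
    truth = HierarchicalTruth(
        lambda_loss=0.01, gamma=0.9, omega=0.95, mechanism=Mechanism.TA
    )
    protocol = PassagingProtocol(n_passages=37)
    curves, truth_table = generate_loss_curves(
        truth, protocol, n_replicates=9, n_events=10_000,
        noise="beta", noise_precision=500.0, seed=42,
    )
    return truth, protocol, curves, truth_table


def random_params(rng, mechanism=None):
    """A random valid parameter set, log-uniform in lambda."""
    mech = mechanism or rng.choice(list(Mechanism))
    return PSKParams(
        lambda_loss=float(10 ** rng.uniform(-6, -0.3)),
        gamma=float(rng.uniform(0.5, 1.5)),
        omega=float(rng.uniform(0, 1)) if mech is not Mechanism.NONE else 0.0,
        mechanism=mech,
    )
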