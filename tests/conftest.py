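import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from worriedwell import (
    default_initial_state,
    default_parameters,
    simulate,
)

DEFAULT_PARAM_DICT = {
    "alpha": 1.0,
    "beta_P": 0.74,
    "beta_W": 0.7,
    "beta_WP": 0.7,
    "gamma_P": 1 / 14,
    "gamma_W": 1 / 14,
    "delta_P": 1 / 240,
}


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def balanced_state():
    return default_initial_state()


@pytest.fixture(scope="session")
def default_trajectory(params, balanced_state):
    """The default 50-week run, shared across tests that only read it."""
    return simulate(params, balanced_state, 350.0)


def random_parameter_dicts(rng: np.random.Generator, n: int) -> list[dict]:
    """Admissible random parameter sets spanning both sides of the threshold."""
    out = []
    for _ in range(n):
        out.append(
            {
                "alpha": rng.uniform(0.1, 3.0),
                "beta_P": rng.uniform(0.0, 1.5),
                "beta_W": rng.uniform(0.0, 1.5),
                "beta_WP": rng.uniform(0.0, 1.5),
                "gamma_P": rng.uniform(0.02, 1.0),
                "gamma_W": rng.uniform(0.02, 1.0),
                "delta_P": rng.uniform(1e-4, 0.5),
            }
        )
    return out
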