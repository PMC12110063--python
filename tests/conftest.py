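import numpy as np
import pytest

from thoughtseeds import make_profile, train
from thoughtseeds.network import extract_network
from thoughtseeds.simulator import run

ENSEMBLE_SEEDS = tuple(range(20))
N_STEPS = 200


class ZeroNoise:
    """Stand-in RNG that produces no noise and no spikes (deterministic paths)."""

    def normal(self, loc=0.0, scale=1.0, size=None):
        return 0.0 if size is None else np.zeros(size)

    def uniform(self, low=0.0, high=1.0, size=None):
        return low if size is None else np.full(size, low)

    def random(self):
        return 1.0  # never below any spike probability


@pytest.fixture(scope="session")
def novice_profile():
    return make_profile("novice")


@pytest.fixture(scope="session")
def expert_profile():
    return make_profile("expert")


@pytest.fixture(scope="session")
def novice_models(novice_profile):
    return [train(novice_profile, n_steps=N_STEPS, seed=s) for s in ENSEMBLE_SEEDS]


@pytest.fixture(scope="session")
def expert_models(expert_profile):
    return [train(expert_profile, n_steps=N_STEPS, seed=s) for s in ENSEMBLE_SEEDS]


def _simulate(models, profile):
    sims = []
    for k, m in enumerate(models):
        alpha = np.array([rec.alpha for rec in m.trace])
        matrix, _ = extract_network(alpha)
        sims.append(run(m, matrix, profile, n_steps=N_STEPS, seed=1000 + k))
    return sims


@pytest.fixture(scope="session")
def novice_sims(novice_models, novice_profile):
    return _simulate(novice_models, novice_profile)


@pytest.fixture(scope="session")
def expert_sims(expert_models, expert_profile):
    return _simulate(expert_models, expert_profile)


@pytest.fixture
def zero_noise():
    return ZeroNoise()
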