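import numpy as np
import pytest

from cmcpatterns.simulate import generate_cohort, stratum_config


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded elsa/male stratum shared by read-only tests (n=800)."""
    cfg = stratum_config("elsa", "male", n=800, seed=42)
    cov, traj, truth = generate_cohort(cfg)
    return cov, traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
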