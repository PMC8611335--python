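import numpy as np
import pytest

from myxomorph import synthetic_data


@pytest.fixture(scope="session")
def small_plate():
    """A small rendered plate with a dozen well-separated bodies."""
    spec = synthetic_data.PlateSpec(
        shape=(256, 256), roi_radius=110.0, n_bodies=12,
        body_radius_mean=6.0, body_radius_sd=0.5,
        interior_mean=120.0, background=200.0, noise_sd=2.0,
    )
    return synthetic_data.render_plate(spec, seed=7)


@pytest.fixture(scope="session")
def sim_tables():
    """Simulated trait table + survival ledger under the default design."""
    spec = synthetic_data.default_evolution_spec()
    traits, ledger = synthetic_data.simulate_evolution(spec, seed=11)
    return traits, ledger


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
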