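import numpy as np
import pytest

from ncrus.pipeline import assemble_samples
from ncrus.simulate import (
    LayerState,
    LeafTraits,
    NoiseConfig,
    simulate_dataset,
)

ZERO_NOISE = NoiseConfig(magnitude_db_std=0.0, phase_rad_std=0.0)


@pytest.fixture(scope="session")
def toy_traits() -> LeafTraits:
    return LeafTraits(
        leaf_id="toy",
        thickness_turgid=380e-6,
        thickness_dry=220e-6,
        speed_turgid=310.0,
        speed_dry=270.0,
        density_turgid=1000.0,
        density_dry=620.0,
        attenuation_turgid=550.0,
        attenuation_dry=1100.0,
        turgid_mass=1.0,
        dry_mass=0.38,
    )


@pytest.fixture(scope="session")
def small_records():
    """A 5-leaf noisy dataset, small enough for fast end-to-end tests."""
    return simulate_dataset(n_leaves=5, total_measurements=45, seed=101)


@pytest.fixture(scope="session")
def small_samples(small_records):
    x, meta = assemble_samples(small_records)
    return x, meta


@pytest.fixture(scope="session")
def noiseless_records():
    return simulate_dataset(n_leaves=3, total_measurements=27, seed=55,
                            noise_cfg=ZERO_NOISE)


def random_layer_state(rng: np.random.Generator) -> LayerState:
    return LayerState(
        thickness=rng.uniform(50e-6, 2e-3),
        speed=rng.uniform(100.0, 3000.0),
        density=rng.uniform(100.0, 3000.0),
        attenuation=rng.uniform(0.0, 5000.0),
        rwc=rng.uniform(0.05, 1.0),
    )
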