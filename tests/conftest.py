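import numpy as np
import pytest

from wsimil.synthetic import SyntheticConfig, generate_cohort, simulate_bags


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """Tiny cohort: fast to simulate, all four classes present."""
    return SyntheticConfig(
        seed=7,
        n_patients_per_class=(6, 6, 6, 6),
        tiles_per_slide_range=(10, 40),
        embed_dim=16,
        diag_fraction=0.3,
        class_separation=6.0,
    )


@pytest.fixture(scope="session")
def small_manifest(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_bags(small_cfg, small_manifest):
    return simulate_bags(small_manifest, small_cfg)
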