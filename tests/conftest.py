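import numpy as np
import pytest

from pestfusion import PreprocessConfig, PyramidSpec, SynthConfig, generate_dataset

DESK_SPEC = PyramidSpec(scale_factor=0.25, width_factor=0.25)
DESK_PREP = PreprocessConfig(H0=16, W0=16, crop_w=12, crop_h=12)


@pytest.fixture(scope="session")
def small_dataset():
    """A small balanced multimodal dataset shared across tests (read-only)."""
    cfg = SynthConfig(n_samples_per_class=(10,) * 6, group_size=5, seed=7)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
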