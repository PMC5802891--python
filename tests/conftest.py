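import numpy as np
import pytest

from bbwosim.config import Config, GridSpec, SyntheticConfig


@pytest.fixture
def small_cfg() -> Config:
    """A 20x20 landscape with a short horizon, for fast process tests."""
    cfg = Config(grid=GridSpec(n_rows=20, n_cols=20, horizon=50))
    cfg.synthetic.n_fire_regions = 2
    cfg.synthetic.n_management_areas = 2
    return cfg


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
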