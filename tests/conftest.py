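import numpy as np
import pytest

import terravalue as tv


@pytest.fixture(scope="session")
def small_landscape() -> tv.Landscape:
    """A 40x40 synthetic landscape with fine patches (many units)."""
    cfg = tv.LandscapeConfig(
        grid=tv.GridSpec(40, 40), patch_scale_m=120.0, corr_length_m=150.0
    )
    return tv.generate_landscape(cfg, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_439)
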