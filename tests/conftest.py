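import numpy as np
import pytest

from graymap import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Slide cohort used by several tests; session-scoped, deterministic."""
    return simulate.synth_cohort(n_per_class=12, seed=42, grid=(12, 12))


@pytest.fixture(scope="session")
def rendered_tiles():
    """One rendered tile + ground truth per IHC class at 256x256."""
    out = {}
    for cls, spec in simulate.CLASS_SPECS.items():
        out[cls] = simulate.render_tile(spec, seed=11, size=256)
    return out
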