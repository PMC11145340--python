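import numpy as np
import pytest

from nucmil.synthetic import ClassParams, SyntheticConfig, generate_slide


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A tiny, fast synthetic configuration for structural tests."""
    return SyntheticConfig(
        seed=7,
        n_slides_per_class=2,
        tiles_per_slide=4,
        tile_size=256,
        nuclei_per_tile=(6, 10),
    )


@pytest.fixture(scope="session")
def positive_slide(small_config):
    return generate_slide(small_config, label=1, index=0)


@pytest.fixture(scope="session")
def negative_slide(small_config):
    return generate_slide(small_config, label=0, index=0)


def random_blob_mask(rng, size=24, n_seeds=40):
    """A random connected-ish binary mask for oracle tests."""
    mask = np.zeros((size, size), dtype=bool)
    ys = rng.integers(0, size, n_seeds)
    xs = rng.integers(0, size, n_seeds)
    mask[ys, xs] = True
    return mask
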