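import numpy as np
import pytest

from gtoscreen.synthetic_fixtures import (
    ImageGenSpec,
    ScreeningGenSpec,
    generate_image_set,
    generate_screening_table,
)


@pytest.fixture(scope="session")
def screening_table():
    """A mid-sized screening table with missing markers (deterministic label)."""
    return generate_screening_table(
        ScreeningGenSpec(n=300, missing_rate=0.05, seed=11)
    )


@pytest.fixture(scope="session")
def clean_table():
    """A small table without missing markers (for round-trip checks)."""
    return generate_screening_table(ScreeningGenSpec(n=60, seed=3))


@pytest.fixture(scope="session")
def image_tree(tmp_path_factory):
    """A small separable two-class PNG tree (15 per class, 64px)."""
    root = tmp_path_factory.mktemp("imgs")
    spec = ImageGenSpec(n_per_class=15, size=64, noise=0.05, seed=21)
    return generate_image_set(spec, root), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
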