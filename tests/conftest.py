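import numpy as np
import pytest

from fosmap.atlas import make_synthetic_atlas
from fosmap.synthetic import ExperimentConfig, generate_slice


@pytest.fixture(scope="session")
def atlas():
    """Small mirror-symmetric test atlas shared across tests."""
    return make_synthetic_atlas(12, (64, 48, 48), (100.0, 100.0, 100.0), seed=20)


@pytest.fixture(scope="session")
def small_atlas():
    return make_synthetic_atlas(8, (48, 40, 40), (100.0, 100.0, 100.0), seed=2)


@pytest.fixture(scope="session")
def rendered_slice(atlas):
    """One synthetic slice with known warp and planted cells (50 µm/px)."""
    config = ExperimentConfig(pixel_size_um=50.0, seed=3)
    rng = np.random.default_rng(5)
    rates = {rid: 30.0 for rid in atlas.hierarchy.leaf_ids()}
    return generate_slice(atlas, ap_um=3050.0, rates_by_channel={"cFos": rates},
                          config=config, rng=rng, subject_id="s1",
                          condition="ctl", slice_id="sl1")
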