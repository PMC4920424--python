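import numpy as np
import pytest

from elytra_id import preprocess, segment, synthdata
from elytra_id.pipeline import build_recovery_dataset, recovery_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo_scene():
    return recovery_scene((480, 640))


@pytest.fixture(scope="session")
def rendered_specimen(demo_scene):
    """One rendered hole-pattern specimen with truth mask and centres."""
    species = synthdata.demo_species()[1]
    img, mask, centers = synthdata.render_specimen(species, demo_scene, seed=7)
    return img, mask, centers


@pytest.fixture(scope="session")
def enhanced_fragment(rendered_specimen):
    """An enhanced, segmented fragment of the rendered specimen."""
    img, _, _ = rendered_specimen
    enhanced = preprocess.enhance(img)
    mask = segment.segment_elytron(enhanced)
    return segment.simulate_fragments(enhanced, mask, n=1, seed=3)[0]


@pytest.fixture(scope="session")
def recovery_dataset():
    """Four-species synthetic collection with all 625 features extracted.

    3 specimens per species, 20 fragments per specimen; shared across the
    classification and acceptance tests because extraction dominates cost.
    """
    return build_recovery_dataset(seed=1)
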