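import numpy as np
import pytest

from scrnet.data_synth import SceneSpec, generate_scene


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same stream regardless of ordering
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scenes():
    """Eight 64x64 scenes with 1-2 large objects (overfit-smoke dataset)."""
    spec = SceneSpec(img_size=64, count_range=(1, 2),
                     obj_frac_range=(0.2, 0.35))
    return [generate_scene(100 + i, spec) for i in range(8)]


@pytest.fixture(scope="session")
def small_models():
    """One model per variant at 64px input, built once per session."""
    from scrnet.assembly import VARIANTS, build_variant
    return {v: build_variant(v, num_classes=4, input_size=64, seed=0)
            for v in VARIANTS}
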