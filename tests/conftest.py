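"""Shared synthetic scenes (session-scoped: they back many tests)."""

import numpy as np
import pytest

from yeastseg import synthgen


@pytest.fixture(scope="session")
def small_scene():
    """A 5-frame colony of ~10 mixed-size cells, phase + truth."""
    params = synthgen.SceneParams(
        n_initial_cells=10, frames=5, frame_shape=(224, 224), rng_seed=2)
    return synthgen.generate_scene(params)


@pytest.fixture(scope="session")
def budding_scene():
    """A 12-frame colony with active budding for tracking/birth tests."""
    params = synthgen.SceneParams(
        n_initial_cells=14, frames=12, frame_shape=(256, 256), rng_seed=1,
        bud_rate=1.0)
    return synthgen.generate_scene(params)


@pytest.fixture(scope="session")
def dense_scene():
    """A dense mature colony (~60 touching cells) for seeding tests."""
    params = synthgen.SceneParams(
        n_initial_cells=60, frames=4, frame_shape=(320, 320), rng_seed=3,
        bud_rate=0.0)
    return synthgen.generate_scene(params)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union
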