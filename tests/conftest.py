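"""Shared fixtures: one default synthetic scene reused across the suite."""

import numpy as np
import pytest

from shadowcwsi.segmentation import build_canopy_internal_shadow_mask
from shadowcwsi.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def scene():
    """Default vineyard preset (19% cover, 43% internal shadow), seed 1."""
    return generate_scene(SceneSpec(seed=1))


@pytest.fixture(scope="session")
def scene_mask(scene):
    """Two-stage canopy / internal-shadow mask of the default scene."""
    return build_canopy_internal_shadow_mask(scene.ms, seed=0)


@pytest.fixture(scope="session")
def registered(scene):
    """Slope-filtered registration of the default scene's thermal frame."""
    from shadowcwsi.registration import register_pair

    return register_pair(scene.ms.band("490"), scene.thermal.band("TIR"))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
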