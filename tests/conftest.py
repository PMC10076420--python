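"""Shared fixtures: small synthetic scenes and rendered masks.

Everything is generated programmatically at fixed seeds; session scope keeps
the expensive scenes shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from laminar.synthetic import BandConfig, SceneConfig, generate_scene


def small_scene_config(seed: int = 11, width: float = 350.0) -> SceneConfig:
    """A narrow section (~3k neurons) keeping the default laminar structure."""
    return SceneConfig(section_width_um=width, seed=seed)


@pytest.fixture(scope="session")
def small_scene():
    """Records + geometry of the narrow default-structure scene."""
    return generate_scene(small_scene_config())


@pytest.fixture(scope="session")
def small_features(small_scene):
    from laminar.neighborhood import build_feature_table

    records, _ = small_scene
    return build_feature_table(records, K=[50, 100, 250], R=8)


@pytest.fixture(scope="session")
def uniform_points():
    rng = np.random.default_rng(42)
    return rng.uniform(0, 1000, size=(500, 2))
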