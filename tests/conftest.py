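"""Shared fixtures: phantom pairs are expensive, so they are session-scoped."""
from __future__ import annotations

import numpy as np
import pytest

from ctmotion import (
    AnalysisConfig,
    PhantomSpec,
    RigidTransform,
    generate_phantom_pair,
    sample_repositioning,
)

#: fast phantom for unit tests: default geometry on a smaller grid
FAST_SHAPE = (72, 72, 72)


@pytest.fixture(scope="session")
def fast_spec() -> PhantomSpec:
    return PhantomSpec(volume_shape=FAST_SHAPE, noise_sd_hu=0.0, seed=42)


@pytest.fixture(scope="session")
def clean_pair(fast_spec):
    """Noise-free pair: 0.5 mm / 1 deg migration, small repositioning."""
    migration = RigidTransform.from_euler([0.0, 0.0, 1.0], [0.5, 0.0, 0.0])
    repositioning = sample_repositioning(2.0, 2.0, seed=7)
    vol1, vol2, gt = generate_phantom_pair(fast_spec, migration, repositioning)
    return vol1, vol2, gt


@pytest.fixture(scope="session")
def noisy_pair():
    """Noise 20 HU, streaks on, same motion as the clean pair."""
    spec = PhantomSpec(volume_shape=FAST_SHAPE, noise_sd_hu=20.0,
                       streak_amplitude_hu=30.0, seed=42)
    migration = RigidTransform.from_euler([0.0, 0.0, 1.0], [0.5, 0.0, 0.0])
    repositioning = sample_repositioning(2.0, 2.0, seed=7)
    vol1, vol2, gt = generate_phantom_pair(spec, migration, repositioning)
    return vol1, vol2, gt


@pytest.fixture(scope="session")
def static_pair(fast_spec):
    """Identity migration and repositioning, noise-free."""
    vol1, vol2, gt = generate_phantom_pair(fast_spec)
    return vol1, vol2, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def config():
    return AnalysisConfig()
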