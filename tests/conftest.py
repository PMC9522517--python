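"""Shared fixtures: seeded scene suites and generator-matched configs.

The heavy artifacts (the 50-scene full-size suite and its pipeline runs) are
session-scoped so the end-to-end and ablation tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prickle import (
    ReferenceColorSet,
    SceneSpec,
    default_config,
    fast_spec,
    generate_scene,
    generate_suite,
    run_pipeline,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def matched_config(scene):
    """Packaged detector defaults with the scene's own prickle palette.

    This is the documented workflow: detector parameters from the packaged
    config, reference colors exported by whoever produced the ground truth
    (here the generator).
    """
    cfg = default_config()
    cfg.reference_colors = ReferenceColorSet(scene.reference_colors())
    return cfg


@pytest.fixture(scope="session")
def suite50():
    """The default 50-scene full-size synthetic suite (seeds 0..49)."""
    return generate_suite(50, SceneSpec())


@pytest.fixture(scope="session")
def partitioned_runs(suite50):
    """Full partitioned pipeline runs on every suite scene, on degraded masks."""
    return [
        (scene, run_pipeline(scene.image, scene.degraded_mask, matched_config(scene)))
        for scene in suite50
    ]


@pytest.fixture(scope="session")
def fast_scenes50():
    """50 scaled-down seeded scenes for mask-recovery and generator tests."""
    return generate_suite(50, fast_spec(1000))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
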