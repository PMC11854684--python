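"""Shared fixtures: one phantom retina and a few rendered ghost images.

Session-scoped because rendering and vessel enhancement dominate test
runtime; every fixture is deterministic (fixed seeds).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ghostgrade.phantom import (
    TrajectoryTruth,
    generate_vessel_phantom,
    render_ghost_image,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phantom():
    return generate_vessel_phantom((512, 512), seed=7)


@pytest.fixture(scope="session")
def single_image(phantom):
    truth = TrajectoryTruth("none", (0.0, 0.0), 0.0, 1, (1.0,), 0.0)
    return render_ghost_image(phantom, truth)


@pytest.fixture(scope="session")
def double_image(phantom):
    truth = TrajectoryTruth(
        "horizontal", (24.0, 0.0), 0.0, 2, (0.5, 0.5), 0.0, amplitude_grade=3
    )
    return render_ghost_image(phantom, truth)


@pytest.fixture(scope="session")
def vertical_double_image(phantom):
    truth = TrajectoryTruth(
        "vertical", (0.0, 20.0), 0.0, 2, (0.5, 0.5), 0.0, amplitude_grade=2
    )
    return render_ghost_image(phantom, truth)


@pytest.fixture(scope="session")
def triple_image(phantom):
    truth = TrajectoryTruth(
        "combined", (12.0, 12.0), 0.0, 3, (1 / 3, 1 / 3, 1 / 3), 0.0, amplitude_grade=2
    )
    return render_ghost_image(phantom, truth)


@pytest.fixture(scope="session")
def rotary_image(phantom):
    truth = TrajectoryTruth(
        "rotary", (0.0, 0.0), 6.0, 2, (0.5, 0.5), 0.0, amplitude_grade=2
    )
    return render_ghost_image(phantom, truth)
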