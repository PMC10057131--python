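"""Shared fixtures: a small landmark surface and a reduced umbrella campaign.

The reduced campaign (36 windows, 800 production samples) keeps the WHAM and
bootstrap tests fast while exercising exactly the same code paths as a full
101-window run.
"""

from __future__ import annotations

import numpy as np
import pytest

from chiralpmf.core import ScheduleSegment, build_window_schedule
from chiralpmf.langevin import LangevinParams, generate_campaign
from chiralpmf.surfaces import surface_from_landmarks
from chiralpmf.wham import WHAMConfig


@pytest.fixture(scope="session")
def small_surface():
    """Asymmetric double well: barrier 4 kcal/mol at RC 0, product at -1.5."""
    return surface_from_landmarks(-1.5, 0.0, 4.0, 1.0, -1.5)


@pytest.fixture(scope="session")
def small_schedule():
    return build_window_schedule(
        [ScheduleSegment(-2.0, 1.5, 0.1)],
        n_equil_samples=200,
        n_prod_samples=800,
    )


@pytest.fixture(scope="session")
def small_campaign(small_surface, small_schedule):
    return generate_campaign(small_surface, small_schedule, LangevinParams(seed=7))


@pytest.fixture()
def wham_config():
    return WHAMConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
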