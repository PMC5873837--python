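"""Shared fixtures: a small synthetic scene library and behavior model.

The library is session-scoped because measuring granularity spectra for
every scene is the expensive step; all tests that need study simulation
share it.  Scenes use 256 px images with the 13-band (cap 128) schedule
and an 80 px annulus outer radius -- a scaled-down version of the field
protocol that keeps the suite fast while preserving every structural
property under test.
"""

import numpy as np
import pandas as pd
import pytest

from camobreak import (
    BehaviorModel,
    build_scene_library,
    default_scene_specs,
)


@pytest.fixture(scope="session")
def scene_library():
    specs = default_scene_specs(24, seed=3, image_size=256)
    return build_scene_library(specs, cap_px=128, outer_radius_px=80)


@pytest.fixture(scope="session")
def behavior():
    return BehaviorModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_events_fixture() -> pd.DataFrame:
    """Five slides: captures with 0/1/2/3 incorrect clicks plus a timeout."""
    rows = []
    for i, clicks in enumerate([0, 1, 2, 3]):
        rows.append(
            {
                "session_id": "S0",
                "viewing_condition": "trichromat",
                "age_class": "16-35",
                "played_before": False,
                "slide_number": i + 1,
                "photo_id": "P0",
                "season": "season0",
                "outcome": "capture",
                "capture_time_s": 2.0 + i,
                "n_incorrect_clicks": clicks,
                "target_cx": 100.0,
                "target_cy": 100.0,
                "edge_distance_px": 100.0,
            }
        )
    rows.append(
        {
            "session_id": "S0",
            "viewing_condition": "trichromat",
            "age_class": "16-35",
            "played_before": False,
            "slide_number": 5,
            "photo_id": "P0",
            "season": "season0",
            "outcome": "timeout",
            "capture_time_s": np.nan,
            "n_incorrect_clicks": 1,
            "target_cx": 100.0,
            "target_cy": 100.0,
            "edge_distance_px": 100.0,
        }
    )
    return pd.DataFrame(rows)


@pytest.fixture()
def five_slide_events() -> pd.DataFrame:
    return make_events_fixture()
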