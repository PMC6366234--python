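"""Shared fixtures: the standard simulated fixture and small helpers.

The *standard fixture* is one full pipeline run (landscape seed 42, 20
birds, default noise and schedules) shared session-wide; several acceptance
criteria and module tests read different artifacts from it, so it is run
once and its outputs are written into a session temp directory.
"""

import numpy as np
import pandas as pd
import pytest

import upliftscape as u

FIXTURE_SEED = 42
FIXTURE_BIRDS = 20


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("standard_fixture")


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir):
    """Full pipeline on the standard fixture, with outputs written."""
    return u.run_pipeline(FIXTURE_SEED, out_dir=fixture_dir,
                          n_birds=FIXTURE_BIRDS)


@pytest.fixture(scope="session")
def fixture_landscape(pipeline_result):
    return pipeline_result["landscape"]


@pytest.fixture(scope="session")
def small_landscape():
    return u.generate_landscape(7, shape=(60, 60))


@pytest.fixture(scope="session")
def small_tracks(small_landscape):
    fixes, acc, truth = u.simulate_tracks(small_landscape, n_birds=3, seed=5)
    return fixes, acc, truth


def make_circle_burst(n_s=150, radius=30.0, period=15.0, climb=1.5,
                      x0=5000.0, y0=5000.0, individual="b1", burst="c1"):
    """1 Hz circling burst: one full circle per ``period`` seconds."""
    t = np.arange(n_s, dtype=float)
    ang = 2 * np.pi * t / period
    return pd.DataFrame({
        "individual_id": individual, "burst_id": burst,
        "timestamp": pd.Timestamp("2014-08-15 08:00:00", tz="UTC")
        + pd.to_timedelta(t, unit="s"),
        "x": x0 + radius * np.cos(ang), "y": y0 + radius * np.sin(ang),
        "lon": 9.0 + (x0 + radius * np.cos(ang)) / 78582.0,
        "lat": 46.0 - (y0 + radius * np.sin(ang)) / 111132.0,
        "height": 500.0 + climb * t,
    })


def make_straight_burst(n_s=150, speed=14.0, vs=-1.0, heading_deg=45.0,
                        x0=2000.0, y0=8000.0, individual="b1", burst="g1"):
    """1 Hz straight (gliding-like) burst."""
    t = np.arange(n_s, dtype=float)
    rad = np.deg2rad(heading_deg)
    x = x0 + speed * t * np.sin(rad)
    y = y0 - speed * t * np.cos(rad)
    return pd.DataFrame({
        "individual_id": individual, "burst_id": burst,
        "timestamp": pd.Timestamp("2014-08-15 09:00:00", tz="UTC")
        + pd.to_timedelta(t, unit="s"),
        "x": x, "y": y,
        "lon": 9.0 + x / 78582.0, "lat": 46.0 - y / 111132.0,
        "height": 800.0 + vs * t,
    })
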