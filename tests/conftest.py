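"""Shared fixtures: a small synthetic landscape and simulated tracks.

Everything is generated at test time from fixed seeds; session scope keeps
the simulation cost paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from fenceline import synth


@pytest.fixture(scope="session")
def small_landscape() -> synth.Landscape:
    return synth.gen_landscape(
        synth.LandscapeConfig(extent=(0.0, 0.0, 12000.0, 12000.0), seed=7)
    )


@pytest.fixture(scope="session")
def small_manifest() -> synth.SimManifest:
    return synth.SimManifest(
        n_animals={"migrant": 2, "resident": 2},
        n_steps=300,
        migrant_range_separation=6000.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_tracks(small_landscape, small_manifest):
    points, sidecar = synth.simulate_tracks(small_landscape, small_manifest)
    return points, sidecar


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
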