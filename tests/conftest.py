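"""Shared fixtures: synthetic scenes and fitted pipeline stages.

The standard benchmark scene and the models fitted on it are expensive,
so they are built once per session and shared across test modules.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from pitt.features import extract_chip, extract_timeseries
from pitt.ki import KIPipeline
from pitt.simulate import small_scene, standard_scene

warnings.filterwarnings("ignore", category=UserWarning)

CLASSES = ("rape", "wheat", "other")


@pytest.fixture(scope="session")
def std_scene():
    """The fixed benchmark scene (seed 7, 600 parcels, 3 classes)."""
    return standard_scene(seed=7)


@pytest.fixture(scope="session")
def std_records(std_scene):
    return {p.id: extract_timeseries(p, std_scene.stack) for p in std_scene.parcels}


@pytest.fixture(scope="session")
def std_ki(std_scene, std_records):
    small = [std_records[i] for i in std_scene.small_ids]
    return KIPipeline(random_state=7).fit(small, std_scene.references)


@pytest.fixture(scope="session")
def std_truth_map(std_scene):
    return std_scene.truth.set_index("parcel_id")["class"]


@pytest.fixture(scope="session")
def std_chips(std_scene):
    """Texture chips: 96 px for small parcels, 8 px for micro parcels."""
    small = [
        extract_chip(std_scene.parcel(i), std_scene.hires, std_scene.hires_grid, side=96)
        for i in std_scene.small_ids
    ]
    micro = [
        extract_chip(std_scene.parcel(i), std_scene.hires, std_scene.hires_grid, side=8)
        for i in std_scene.micro_ids
    ]
    return {"small": small, "micro": micro}


@pytest.fixture(scope="session")
def tiny_scene():
    """Reduced scene for fast structural tests."""
    return small_scene(seed=0, per_group=8)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
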