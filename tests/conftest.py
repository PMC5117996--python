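"""Shared fixtures: small synthetic acquisitions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from msemstitch.model import build_overlap_graph
from msemstitch.pipeline import align_all
from msemstitch.synthetic import (
    AcquisitionSpec,
    SceneSpec,
    generate_acquisition,
    generate_scene,
    required_scene_size,
)


def make_acquisition(
    mfov_grid=(1, 1),
    tiles_per_mfov=19,
    jitter_sigma=5.0,
    seed=2,
    overlap_fraction=0.06,
    artifacts=(),
):
    spec = AcquisitionSpec(
        mfov_grid=mfov_grid,
        tiles_per_mfov=tiles_per_mfov,
        overlap_fraction=overlap_fraction,
        jitter_sigma=jitter_sigma,
        artifacts=list(artifacts),
        seed=seed,
    )
    scene = generate_scene(SceneSpec(size=required_scene_size(spec), seed=seed))
    return generate_acquisition(scene, spec)


@pytest.fixture(scope="session")
def mfov19():
    """One 19-tile hexagonal mFOV, 6% overlap, 5 px stage jitter."""
    return make_acquisition()


@pytest.fixture(scope="session")
def mfov19_aligned(mfov19):
    """The same acquisition with its overlap graph phase-correlated."""
    pairs = build_overlap_graph(mfov19.tiles)
    return align_all(mfov19.tiles, pairs, margin=60)


@pytest.fixture(scope="session")
def mfov61():
    """One full 61-tile mFOV with 15 px jitter (the nominal conditions)."""
    return make_acquisition(tiles_per_mfov=61, jitter_sigma=15.0, seed=3)
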