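"""Shared fixtures: default phantom, geometry, schedule and input function."""

import numpy as np
import pytest

from petmoco import (FrameSchedule, InputFunction, MotionPhaseSpec, Phantom,
                     PhantomConfig, ProjectionGeometry, build_phantom)


@pytest.fixture(scope="session")
def phantom() -> Phantom:
    return build_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def crm_spec() -> MotionPhaseSpec:
    return MotionPhaseSpec.crm()


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return FrameSchedule()


@pytest.fixture(scope="session")
def aif() -> InputFunction:
    return InputFunction()


@pytest.fixture(scope="session")
def geometry() -> ProjectionGeometry:
    return ProjectionGeometry()


@pytest.fixture(scope="session")
def small_geometry() -> ProjectionGeometry:
    """Coarse geometry for fast projector/recon tests."""
    return ProjectionGeometry(n_angles=90, n_radial=63, radial_bin_size=3.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
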