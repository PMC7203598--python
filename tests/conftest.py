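import numpy as np
import pytest

import osteoadapt as oa

#: Body mass (g) used for phantom load cases; mid-range for adult C57BL/6 mice.
BODY_MASS = 19.5

#: Recovery-experiment truth, scaled to the phantom's surface SED distribution
#: (median ~10 kPa under the walking load; see docs/methods.md).
TRUE_B = 0.01
TRUE_K = 10_000.0
B_RANGE = (1e-3, 0.1)
K_RANGE = (1_000.0, 50_000.0)


def small_spec(seed: int = 1) -> oa.PhantomSpec:
    """Fast cortical-tube phantom used throughout the unit tests."""
    return oa.PhantomSpec(shape=(32, 32, 64), outer_radius=(9.0, 8.0),
                          wall=(4.0, 4.0), seed=seed)


@pytest.fixture(scope="session")
def cal() -> oa.DensitometricCalibration:
    return oa.default_calibration()


@pytest.fixture(scope="session")
def stim_cache() -> oa.StimulusCache:
    """Session-wide FE stimulus cache: the stimulus of a fixed mask/load is
    deterministic, so tests sharing a phantom share one solve."""
    return oa.StimulusCache(maxsize=16)


@pytest.fixture(scope="session")
def small_phantom(cal) -> oa.VoxelImage:
    return oa.make_phantom(small_spec(), cal)


@pytest.fixture(scope="session")
def small_seg(small_phantom) -> oa.SegmentationModel:
    return oa.SegmentationModel.from_image(small_phantom)


@pytest.fixture(scope="session")
def default_phantom(cal) -> oa.VoxelImage:
    """The full-size (40 x 40 x 120) tube phantom."""
    return oa.make_phantom(oa.PhantomSpec(), cal)


@pytest.fixture(scope="session")
def default_seg(default_phantom) -> oa.SegmentationModel:
    return oa.SegmentationModel.from_image(default_phantom)


@pytest.fixture(scope="session")
def tube_mask() -> oa.BoneMask:
    """Closed hollow tube mask for surface/morphometry tests."""
    return oa.make_fixture("annulus", r_out=8.0, r_in=5.0, height=8)
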