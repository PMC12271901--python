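"""Shared fixtures: a small fast phantom and a coarse protocol."""

import numpy as np
import pytest

from smsperf.phantom import (BolusModel, MotionConfig, PhantomSpec,
                             make_motion_trace, make_phantom)
from smsperf.sequence import Protocol


@pytest.fixture(scope="session")
def small_spec():
    # 64^3-ish grid, coarse voxels covering the same world geometry.
    return PhantomSpec(grid_shape=(64, 64, 64), voxel_size=(3.8, 3.8, 3.0))


@pytest.fixture(scope="session")
def static_phantom(small_spec):
    motion = make_motion_trace(
        MotionConfig(amplitude_mm=0.0, drift_mm_per_s=0.0), 60.0)
    return make_phantom(small_spec, motion=motion)


@pytest.fixture(scope="session")
def quiet_phantom(small_spec):
    """No motion and no contrast passage: a truly time-invariant object."""
    motion = make_motion_trace(
        MotionConfig(amplitude_mm=0.0, drift_mm_per_s=0.0), 60.0)
    return make_phantom(small_spec, bolus=BolusModel(peak_amplitude_mmol=0.0),
                        motion=motion)


@pytest.fixture(scope="session")
def breathing_phantom(small_spec):
    motion = make_motion_trace(
        MotionConfig(amplitude_mm=7.0, period_s=4.0, drift_mm_per_s=0.0), 60.0)
    return make_phantom(small_spec, motion=motion)


@pytest.fixture(scope="session")
def small_protocol():
    return Protocol(n_read=64, n_pe=64, n_dynamics=8, n_slices=6,
                    multiband=2, inplane_accel=3.5, sr_blocks_per_beat=3)


@pytest.fixture(scope="session")
def midslice_weights(static_phantom):
    return static_phantom.tissue_weights(20.0, 100.0)
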