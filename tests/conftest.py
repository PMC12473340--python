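import numpy as np
import pytest

from qmtkit.mt_physics import RFPulse, TwoPoolParams
from qmtkit.synthetic import (
    MULTIOFFSET_FLIPS,
    MULTIOFFSET_OFFSETS_HZ,
    SINGLEOFFSET_FLIP,
)


@pytest.fixture
def mt_pulse():
    """The study's standard multi-offset MT pulse at 500 deg / 1 kHz."""
    return RFPulse(
        flip_angle_deg=500.0,
        duration_s=10.24e-3,
        bandwidth_hz=200.0,
        offset_hz=1e3,
        tr_s=0.05,
    )


@pytest.fixture
def single_offset_pulse():
    """The single-offset protocol pulse: 650 deg at 1 kHz."""
    return RFPulse(
        flip_angle_deg=SINGLEOFFSET_FLIP,
        duration_s=10.24e-3,
        bandwidth_hz=200.0,
        offset_hz=1e3,
        tr_s=0.05,
    )


@pytest.fixture
def muscle_params():
    """Muscle-like two-pool truth (young calf scale)."""
    return TwoPoolParams(F=0.07, rm0a=48.0, RA=0.7, T2A=0.035, T2B=6e-6)


@pytest.fixture
def protocol_pulses():
    """The 14 multi-offset protocol pulses (350/500 deg x 7 offsets)."""
    return [
        RFPulse(flip_angle_deg=flip, duration_s=10.24e-3, bandwidth_hz=200.0, offset_hz=off, tr_s=0.05)
        for flip in MULTIOFFSET_FLIPS
        for off in MULTIOFFSET_OFFSETS_HZ
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
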