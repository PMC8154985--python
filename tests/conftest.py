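import numpy as np
import pytest

from etlscan.etl import AcquisitionGeometry
from etlscan.responses import StimulusProtocol
from etlscan.synthetic import ActivityModel


@pytest.fixture
def whole_brain_geometry():
    """The canonical whole-brain configuration."""
    return AcquisitionGeometry()


@pytest.fixture
def small_geometry():
    """A miniature volume for fast rendered tests."""
    return AcquisitionGeometry(
        fov_x=50.0, fov_y=50.0, z_range=60.0, n_x=64, n_y=64, n_planes=6, frame_rate=6.0
    )


@pytest.fixture
def looming_protocol():
    """10 presentations, 150 s apart, 17 s each."""
    return StimulusProtocol.looming()


@pytest.fixture
def short_protocol():
    return StimulusProtocol.looming(
        n_presentations=3, interval=30.0, stim_duration=5.0, first_onset=10.0
    )


@pytest.fixture
def default_model():
    return ActivityModel(photon_gain=100.0)


def f1_score(selected: np.ndarray, truth: np.ndarray) -> float:
    tp = int((selected & truth).sum())
    fp = int((selected & ~truth).sum())
    fn = int((~selected & truth).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0
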