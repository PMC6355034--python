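import numpy as np
import pytest

from casakit import AnalysisSettings
from casakit.tracks import Trajectory


@pytest.fixture
def settings():
    return AnalysisSettings()


def make_traj(points, track_id=0, **kwargs):
    pts = np.asarray(points, dtype=float)
    return Trajectory(track_id=track_id, points=pts, frames=np.arange(len(pts)), **kwargs)


@pytest.fixture
def make_trajectory():
    return make_traj
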