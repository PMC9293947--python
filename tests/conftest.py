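import numpy as np
import pytest

from hypomimia.io import LandmarkSequence
from hypomimia.synth import SyntheticCohortConfig, face_template


def make_sequence(coords, fps=25.0, valid=None, width=1440, height=1080,
                  subject_id="test"):
    coords = np.asarray(coords, dtype=float)
    if valid is None:
        valid = np.ones(coords.shape[:2], dtype=bool)
    return LandmarkSequence(subject_id=subject_id, fps=fps, coords=coords,
                            valid=valid, width=width, height=height)


@pytest.fixture
def neutral_face():
    """Neutral template in pixels: IED = 100 px, centred in a 1440x1080 frame."""
    return face_template() * 100.0 + np.array([720.0, 400.0])


@pytest.fixture
def static_seq(neutral_face):
    """A 10-frame perfectly static recording."""
    return make_sequence(np.broadcast_to(neutral_face, (10, 68, 2)).copy())


@pytest.fixture
def small_config():
    """Desk-scale synthetic recording conditions: 4 s, 25 fps, 160x120."""
    return SyntheticCohortConfig(
        n_controls=2, n_patients=2, duration=4.0, fps=25.0,
        width=160, height=120, ied_px=17.0, seed=0,
    )
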