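import numpy as np
import pandas as pd
import pytest

from poseactivity import CohortSpec, SessionRecording, generate_cohort
from poseactivity.landmarks import N_LANDMARKS
from poseactivity.synthetic import BASE_POSE


def base_pose_array() -> np.ndarray:
    return np.array([BASE_POSE[i] for i in range(N_LANDMARKS)])


def static_session(n_frames: int = 60, fps: float = 30.0, pid: str = "static") -> SessionRecording:
    """A motionless session at the seated base pose, full confidence."""
    xyz = np.tile(base_pose_array(), (n_frames, 1, 1))
    conf = np.ones((n_frames, N_LANDMARKS))
    return SessionRecording(participant_id=pid, fps=fps, xyz=xyz, confidence=conf)


@pytest.fixture
def tiny_spec() -> CohortSpec:
    """A short, small cohort for fast end-to-end tests."""
    return CohortSpec(n_risk=6, n_control=8, duration_s=10.0, seed=123)


@pytest.fixture
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def feature_cohort():
    """A moderately sized cohort with realistic group structure, shared
    across classification tests (session-scoped: generated once)."""
    from poseactivity.kinematics import build_feature_table

    spec = CohortSpec(n_risk=20, n_control=31, duration_s=15.0, seed=7)
    sessions, meta = generate_cohort(spec)
    features, _ = build_feature_table(sessions, meta)
    return features
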