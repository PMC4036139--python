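import numpy as np
import pytest

import electrokin as ek


@pytest.fixture(scope="session")
def default_config():
    return ek.GeneratorConfig(n_frames_target=12_000, seed=3)


@pytest.fixture(scope="session")
def object_session(default_config):
    return ek.generate_session(default_config, seed=3)


@pytest.fixture(scope="session")
def no_object_session(default_config):
    return ek.generate_session(default_config.replace(object_present=False), seed=4)


@pytest.fixture(scope="session")
def object_kinematics(object_session):
    return ek.compute_kinematics(object_session)


@pytest.fixture(scope="session")
def fitted_scaler(object_kinematics):
    return ek.fit_scaler(object_kinematics)


def make_session(x, y, heading, t=None, frame_index=None, session_id="T"):
    """Hand-built session helper for kinematics tests."""
    x = np.asarray(x, dtype=float)
    if t is None:
        t = 0.04 * np.arange(len(x))
    if frame_index is None:
        frame_index = np.arange(len(x))
    return ek.TrackedSession(
        session_id=session_id, fish_id="F", night_id="N", condition="object",
        frame_index=np.asarray(frame_index), t=np.asarray(t, dtype=float),
        x=x, y=np.asarray(y, dtype=float), heading=np.asarray(heading, dtype=float),
    )
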