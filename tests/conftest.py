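import numpy as np
import pytest

from bicar.game import ControllerConfig
from bicar.kinematics import RobotGeometry
from bicar.simulate import healthy_profile, post_stroke_profile, simulate_session


@pytest.fixture(scope="session")
def geom():
    return RobotGeometry(frame_width_Wb=1.0, handlebar_width_Wg=0.5)


@pytest.fixture(scope="session")
def healthy_log():
    """A healthy subject playing MineCart for five minutes."""
    return simulate_session(
        healthy_profile(), ControllerConfig(), duration=300.0, seed=7
    )


@pytest.fixture(scope="session")
def stroke_log():
    """A left-hemiparetic subject playing MineCart for five minutes."""
    return simulate_session(
        post_stroke_profile("left", severity=0.4),
        ControllerConfig(),
        duration=300.0,
        seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
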