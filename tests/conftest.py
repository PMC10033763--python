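import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def open_field_5x5():
    from navrl.envs import make_open_field

    return make_open_field(5, 5, goal_state=24, goal_reward=1.0)


@pytest.fixture
def t_maze():
    from navrl.envs import make_t_maze

    return make_t_maze(3, 2, "right", 1.0)


@pytest.fixture
def blodgett():
    from navrl.envs import make_blodgett_maze

    return make_blodgett_maze()
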