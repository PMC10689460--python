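import numpy as np
import pytest

from lamevo.body import (
    BRICK,
    CORE,
    HINGE,
    BodyModule,
    RobotBody,
    decode_body,
)
from lamevo.env import SurrogateBackend, TaskSpec
from lamevo.fixtures import cppn_chain10, cppn_core_only, cppn_plus


@pytest.fixture(scope="session")
def core_only_body():
    return decode_body(cppn_core_only())


@pytest.fixture(scope="session")
def plus_body():
    """Four active hinges around the core: (+-1,0,0) and (0,+-1,0)."""
    return decode_body(cppn_plus())


@pytest.fixture(scope="session")
def chain_body():
    """Straight chain of ten active hinges along +y."""
    return decode_body(cppn_chain10())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def backend():
    return SurrogateBackend()


@pytest.fixture(scope="session")
def task():
    return TaskSpec()


def make_single_hinge_body() -> RobotBody:
    """Hand-built body: core with one hinge on its front socket."""
    core = BodyModule(CORE, (0, 0, 0), 0, None, None, 0)
    hinge = BodyModule(HINGE, (0, 1, 0), 0, 0, 0, 1)
    core.children.append(1)
    body = RobotBody([core, hinge])
    body.validate()
    return body


def make_stacked_joints_body() -> RobotBody:
    """Two hinges sharing the same (x, y) after the z dimension is dropped:
    a brick at (1,0,0) carries one hinge above and one below, both at 2D
    cell (1, 0) and at tree distance 2 from each other."""
    core = BodyModule(CORE, (0, 0, 0), 0, None, None, 0)
    brick = BodyModule(BRICK, (1, 0, 0), 0, 0, 3, 1)
    h_up = BodyModule(HINGE, (1, 0, 1), 0, 1, 3, 2)
    h_down = BodyModule(HINGE, (1, 0, -1), 0, 1, 4, 2)
    core.children.append(1)
    brick.children.extend([2, 3])
    body = RobotBody([core, brick, h_up, h_down])
    body.validate()
    return body
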