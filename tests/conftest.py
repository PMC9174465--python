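import numpy as np
import pytest

from mocapuq.model import JointSpec, LinkSegmentModel, MarkerRegistration, Segment
from mocapuq.synthetic import default_gait_model, generate_trial


@pytest.fixture(scope="session")
def gait_model():
    return default_gait_model()


@pytest.fixture(scope="session")
def trial():
    """Noise-free synthetic walking trial (100 frames at 100 Hz)."""
    return generate_trial(seed=1)


def make_pendulum(
    mass=2.0, com_d=0.5, inertia_zz=0.0, axis=(0.0, 0.0, 1.0), name="pendulum"
):
    """Single pin-jointed segment hanging along -y; marker at the tip."""
    seg = Segment(
        name="rod",
        parent=None,
        joint=JointSpec(
            type="pin", axes=(tuple(axis),), coordinate_names=("theta",)
        ),
        location_in_parent=(0.0, 0.0, 0.0),
        mass=mass,
        com=(0.0, -com_d, 0.0),
        inertia=((0.0,) * 3, (0.0,) * 3, (0.0, 0.0, inertia_zz)),
    )
    markers = (
        MarkerRegistration("tip", "rod", (0.0, -2 * com_d, 0.0)),
        MarkerRegistration("mid", "rod", (0.0, -com_d, 0.05)),
        MarkerRegistration("base", "rod", (0.05, 0.0, 0.0)),
    )
    return LinkSegmentModel(name=name, segments=(seg,), markers=markers)


@pytest.fixture
def pendulum():
    return make_pendulum()


@pytest.fixture
def free_body():
    """A single free-floating segment with four non-coplanar markers."""
    seg = Segment(
        name="box",
        parent=None,
        joint=JointSpec(
            type="free",
            axes=((0, 0, 1), (1, 0, 0), (0, 1, 0)),
            coordinate_names=("tx", "ty", "tz", "rz", "rx", "ry"),
        ),
        location_in_parent=(0.0, 0.0, 0.0),
        mass=1.0,
        com=(0.0, 0.0, 0.0),
        inertia=np.diag([0.01, 0.01, 0.01]).tolist(),
    )
    markers = tuple(
        MarkerRegistration(f"m{i}", "box", p)
        for i, p in enumerate(
            [(0.1, 0, 0), (0, 0.12, 0), (0, 0, 0.15), (0.05, 0.06, 0.07)]
        )
    )
    return LinkSegmentModel(name="freebody", segments=(seg,), markers=markers)
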