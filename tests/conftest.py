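import numpy as np
import pytest

from cardiokit.cell_models import get_model
from cardiokit.ep_solver import EPSystem, Stimulus, StimulusProtocol
from cardiokit.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def cable20():
    """20 mm cable at 0.1 mm resolution (200 cells)."""
    return make_fixture(FixtureSpec("cable", (20.0,), 0.1))


@pytest.fixture(scope="session")
def minimal_model():
    return get_model("minimal")


def isotropic_tensors(n, m):
    return m * np.broadcast_to(np.eye(3), (n, 3, 3)).copy()


def run_cable_wave(mesh, model, m_scalar, chi_cm, dt=0.05, T=120.0,
                   amp=5.0, n_stim=5, theta=0.5, record_every=0):
    """Stimulate one cable end and march until full activation."""
    proto = StimulusProtocol([Stimulus(cells=tuple(range(n_stim)),
                                       onset=0.0, duration=2.0,
                                       amplitude=amp)])
    sys_ = EPSystem(mesh, isotropic_tensors(mesh.n_cells, m_scalar), model,
                    chi_cm=chi_cm, protocol=proto, theta=theta)
    frames, ftimes = [], []
    k = 0
    while sys_.t < T:
        sys_.step(dt)
        k += 1
        if record_every and k % record_every == 0:
            frames.append(sys_.v.copy())
            ftimes.append(sys_.t)
        if not record_every and sys_.activation.activated.all():
            break
    sys_._frames = frames
    sys_._frame_times = np.asarray(ftimes)
    return sys_
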