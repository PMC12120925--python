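import numpy as np
import pytest

from disuse.datamodel import BoldRun, MotionTrace, StudyConfig
from disuse.simulate import SimParams, make_space, make_truth


@pytest.fixture(scope="session")
def tiny_params():
    """A small but structurally complete synthetic study configuration."""
    return SimParams(
        cortex_shape=(8, 8), thalamus_shape=(3, 3, 3),
        putamen_shape=(2, 2, 2), pallidum_shape=(2, 2, 2),
        caudate_shape=(2, 2, 2), cerebellum_shape=(3, 3, 3),
        T=150, sessions_per_phase=3, fc_blob_size=20,
    )


@pytest.fixture(scope="session")
def tiny_space(tiny_params):
    return make_space(tiny_params, seed=0)


@pytest.fixture(scope="session")
def tiny_truth(tiny_params, tiny_space):
    return make_truth(tiny_space, tiny_params, seed=0)


@pytest.fixture(scope="session")
def default_params():
    return SimParams()


@pytest.fixture(scope="session")
def default_space(default_params):
    return make_space(default_params, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_run(data, tr=1.1, phase="pre", session_id="s1", fd=None):
    data = np.asarray(data, dtype=float)
    T = data.shape[1]
    if fd is None:
        fd = np.zeros(T)
    return BoldRun(
        data=data, tr_seconds=tr, session_id=session_id, phase=phase,
        motion=MotionTrace(fd_mm=np.asarray(fd, dtype=float),
                           params6=np.zeros((T, 6))),
    )


@pytest.fixture
def noise_run(rng):
    return make_run(rng.standard_normal((30, 200)))
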