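import numpy as np
import pytest

import unitflow as uf


@pytest.fixture(scope="session")
def fig1():
    return uf.build_fig1(seed=0)


@pytest.fixture(scope="session")
def example2():
    return uf.build_example2(seed=0)


@pytest.fixture(scope="session")
def example2_record(example2):
    return example2.run(n_grid=301)


@pytest.fixture(scope="session")
def walker():
    return uf.build_walker(L=2, ncg=4, seed=0)


@pytest.fixture(scope="session")
def walker_record(walker):
    return walker.run(n_grid=61)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def controlled_example2(seed=0, eps=0.0):
    """Three-subsystem fixture extended with a controller that measures x2
    through a symmetric channel of error eps; the dynamics ignores c."""
    bundle = uf.build_example2(seed=seed)
    sp = bundle.system.space
    m = np.empty((2, sp.size))
    for i, s in enumerate(sp.states()):
        x2 = s[1]
        m[:, i] = [1 - eps if x2 == 0 else eps,
                   eps if x2 == 0 else 1 - eps]
    ch = uf.Channel(sp, m)
    ext = uf.controlled_system(ch, bundle.system.reservoirs)
    p_ti = uf.joint_initial(bundle.initial, ch)
    rec = uf.evolve(ext, p_ti, bundle.ti, bundle.tf, n_grid=201)
    return bundle, ext, p_ti, rec.final


def two_state_space():
    return uf.JointSpace([uf.Coordinate("s", 2)])


@pytest.fixture()
def bit_pair():
    return uf.JointSpace([uf.Coordinate("a", 2), uf.Coordinate("b", 2)])
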