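import numpy as np
import pytest

import nuclens as nl


@pytest.fixture(scope="session")
def diatomic():
    """Toy homonuclear diatomic: (molecule, hessian, analytic wavenumbers)."""
    return nl.make_toy_hessian(nl.ToySpec(kind="diatomic", k_bond=0.3))


@pytest.fixture(scope="session")
def bent_triatomic():
    return nl.make_toy_hessian(nl.ToySpec(kind="bent-triatomic"))


@pytest.fixture(scope="session")
def enone_chain():
    return nl.make_toy_hessian(nl.ToySpec(kind="enone-chain"))


@pytest.fixture(scope="session")
def diatomic_modes(diatomic):
    return nl.normal_mode_analysis(diatomic[1])


@pytest.fixture(scope="session")
def enone_modes(enone_chain):
    return nl.normal_mode_analysis(enone_chain[1])


@pytest.fixture(scope="session")
def table1():
    """The packaged worked-example transition table (one geometry, 9 states)."""
    return nl.load_u6oh_table1()


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
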