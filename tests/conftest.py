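"""Shared, session-scoped fixture molecules.

The builders are deterministic in (name, seed); building them once per
session keeps the suite fast.  Tests treat these objects as read-only:
anything that mutates a molecule (fixing atoms, adding restraints)
constructs its own copy.
"""

import numpy as np
import pytest

from molsample.fixtures import make_fixture


@pytest.fixture(scope="session")
def butane_fx():
    return make_fixture("butane", 7)


@pytest.fixture(scope="session")
def chiral_fx():
    return make_fixture("chiral_probe", 7)


@pytest.fixture(scope="session")
def dipeptide_fx():
    return make_fixture("cyclic_dipeptide", 7)


@pytest.fixture(scope="session")
def symmetric_fx():
    return make_fixture("symmetric_ligand", 7)


@pytest.fixture(scope="session")
def cavity_hydro_fx():
    return make_fixture("cavity_hydrophobic", 2)


@pytest.fixture(scope="session")
def cavity_polar_fx():
    return make_fixture("cavity_polar_decoy", 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
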