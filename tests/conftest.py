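"""Shared fixtures: one ground-truth synthetic two-domain system reused by
the linker, selection and integration tests (building it is the expensive
step), plus the packaged restraint table and label model."""

import numpy as np
import pytest

from deerdock.labelmodel import LabelModel
from deerdock.posesearch import Pose
from deerdock.restraints import packaged_table3
from deerdock import synthdata

#: grid-commensurate arrangement used by the shared system: translation on
#: the 2 A lattice, rotation from the reduced orientation grid, and a
#: fixed-C-terminus to moving-N-terminus span a 23-residue linker can close
TRUE_POSE = Pose(2.8838585128841387, 2.040229617203016, np.pi,
                 (22.0, 26.0, -6.0))
SYSTEM_SEED = 3


@pytest.fixture(scope="session")
def system():
    return synthdata.make_two_domain_system(TRUE_POSE, seed=SYSTEM_SEED,
                                            n_residues=40)


@pytest.fixture(scope="session")
def noiseless_restraints(system):
    return synthdata.simulate_deer_means(system, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def table3():
    return packaged_table3()


@pytest.fixture(scope="session")
def mtsl():
    return LabelModel.default_mtsl()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
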