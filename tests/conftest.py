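"""Shared fixtures: small synthetic systems with known ground truth."""

import numpy as np
import pytest

from pidrtools import synthetic as S
from pidrtools.membrane import assign_leaflets


@pytest.fixture(scope="session")
def ref_system():
    """A 200-frame study-condition system (two substates, 30/70)."""
    return S.make_reference_system(n_frames=200, seed=23)


@pytest.fixture(scope="session")
def ref_traj(ref_system):
    return ref_system[0]


@pytest.fixture(scope="session")
def ref_gt(ref_system):
    return ref_system[1]


@pytest.fixture(scope="session")
def ref_leaflets(ref_traj):
    return assign_leaflets(ref_traj.frame(0), ref_traj.topology)


@pytest.fixture(scope="session")
def tiny_system():
    """A 5-frame system for I/O and structural tests."""
    return S.make_reference_system(n_frames=5, seed=7)
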