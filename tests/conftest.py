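"""Shared fixtures: morphologies, parameter vectors, passive cells."""

import numpy as np
import pytest

from ca3deg.morphology import (
    Section,
    SectionTree,
    build_synthetic_morphology,
    discretize,
)
from ca3deg.mpmoss import ParameterVector


@pytest.fixture(scope="session")
def tree():
    return build_synthetic_morphology()


@pytest.fixture(scope="session")
def model(tree):
    return discretize(tree)


@pytest.fixture(scope="session")
def base_params():
    return ParameterVector()


@pytest.fixture(scope="session")
def passive_params():
    """All active conductances zeroed: a purely passive cable."""
    return ParameterVector(
        g_na=0.0, g_kdr=0.0, g_h=0.0, g_ka=0.0, g_cal=0.0, g_cat=0.0,
        g_can=0.0, g_km=0.0, g_bk=0.0, g_sk=0.0,
    )


@pytest.fixture()
def single_soma():
    """One spherical soma (20 µm), discretized to a single compartment."""
    t = SectionTree([Section(0, -1, "soma", np.array([[0.0, 0.0, 0.0, 20.0]]))])
    return discretize(t)


@pytest.fixture()
def stick_tree():
    """Soma plus a single 400 µm apical cylinder."""
    return SectionTree([
        Section(0, -1, "soma", np.array([[0.0, 0.0, 0.0, 20.0]])),
        Section(1, 0, "apical",
                np.array([[0.0, 10.0, 0.0, 2.0], [0.0, 410.0, 0.0, 2.0]])),
    ])
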