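"""Shared fixtures: generated topologies are expensive, so each fixture
molecule is built once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from qctviz import GenerationOptions, build_fixture_geometry, generate_topology
from qctviz.density import PromolecularDensity
from qctviz.search import find_critical_points

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def h2_density():
    return PromolecularDensity(build_fixture_geometry("h2").nuclei)


@pytest.fixture(scope="session")
def benzene_density():
    return PromolecularDensity(build_fixture_geometry("benzene").nuclei)


@pytest.fixture(scope="session")
def benzene_cps(benzene_density):
    return find_critical_points(benzene_density)


@pytest.fixture(scope="session")
def h2_full_topology():
    """H2 with every optional component generated (basins, interatomic
    surface, envelopes)."""
    return generate_topology(
        build_fixture_geometry("h2"),
        GenerationOptions(basins=True, interatomic_surfaces=True, envelopes=True))


@pytest.fixture(scope="session")
def hcn_topology():
    return generate_topology(build_fixture_geometry("hcn"),
                             GenerationOptions(basins=True))


@pytest.fixture(scope="session")
def benzene_topology():
    return generate_topology(build_fixture_geometry("benzene"))


@pytest.fixture(scope="session")
def hf5_topology():
    return generate_topology(build_fixture_geometry("hf_pentamer"))


@pytest.fixture(scope="session")
def s8_topology():
    return generate_topology(build_fixture_geometry("s8"))


@pytest.fixture(scope="session")
def hex_topology():
    return generate_topology(build_fixture_geometry("hexamethylenetetramine"))


@pytest.fixture(scope="session")
def hfh_ias_topology():
    return generate_topology(build_fixture_geometry("hfh_anion"),
                             GenerationOptions(interatomic_surfaces=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)
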