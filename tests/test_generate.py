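"""Topology generation pipeline: molecular graphs, rings, cages,
basins, envelopes and interatomic surfaces on the fixture molecules."""

import math

import numpy as np
import pytest

from qctviz.density import PromolecularDensity
from qctviz.fixtures import build_fixture_geometry
from qctviz.generate import (
    GenerationOptions,
    build_envelope,
    build_interatomic_surface,
    generate_topology,
)
from qctviz.model import INFINITY, Nucleus, TopologyError
from qctviz.search import find_critical_points, trace_gradient_path


def test_benzene_molecular_graph(benzene_topology):
    g = benzene_topology.gvf
    assert len(g.molecular_graph.ails) == 12
    assert len(g.rings) == 1
    # only the 6 C-C interaction lines close the ring; C-H lines are excluded
    assert len(g.rings[0].ails) == 6
    ring_nodes = set()
    for ai in g.rings[0].ails:
        ring_nodes.update(g.molecular_graph.ails[ai].nacp_pair())
    carbons = {i for i, cp in enumerate(benzene_topology.critical_points)
               if cp.is_nacp and i < 6}
    assert ring_nodes == carbons


def test_hf_pentamer_graph_and_ring(hf5_topology):
    g = hf5_topology.gvf
    assert len(g.molecular_graph.ails) == 10
    assert len(g.rings) == 1
    assert len(g.rings[0].ails) == 10


def test_s8_ring(s8_topology):
    g = s8_topology.gvf
    assert len(g.molecular_graph.ails) == 8
    assert len(g.rings) == 1
    assert len(g.rings[0].ails) == 8


def test_hcn_is_acyclic(hcn_topology):
    g = hcn_topology.gvf
    assert len(g.molecular_graph.ails) == 2
    assert g.rings == []
    assert g.cages == []
    assert len(g.basins) == 3
    assert hcn_topology.poincare_hopf_residual() == 1


def test_hexamethylenetetramine_rings_and_cage(hex_topology):
    """Four six-membered rings enclosing the central cage CP."""
    g = hex_topology.gvf
    assert len(g.molecular_graph.ails) == 24
    assert len(g.rings) == 4
    assert all(len(r.ails) == 6 for r in g.rings)
    assert len(g.cages) == 1
    assert sorted(g.cages[0].rings) == [0, 1, 2, 3]
    ccp = hex_topology.critical_points[g.cages[0].ccp]
    assert ccp.is_ccp
    # the genuine cage CP is the central one
    centroid = np.array([n.position for n in hex_topology.nuclei]).mean(axis=0)
    assert np.linalg.norm(ccp.position - centroid) < 1e-6


@pytest.mark.parametrize("topology_fixture", [
    "hcn_topology", "benzene_topology", "hf5_topology", "s8_topology",
    "hex_topology", "h2_full_topology",
])
def test_poincare_hopf_holds_on_all_fixtures(topology_fixture, request):
    top = request.getfixturevalue(topology_fixture)
    assert top.poincare_hopf_residual() == 1


@pytest.mark.parametrize("topology_fixture", [
    "hcn_topology", "benzene_topology", "hf5_topology", "hex_topology",
])
def test_every_ail_connects_two_distinct_nacps(topology_fixture, request):
    top = request.getfixturevalue(topology_fixture)
    for ail in top.gvf.molecular_graph.ails:
        a, b = ail.nacp_pair()
        assert a != b
        assert top.critical_points[a].is_nacp
        assert top.critical_points[b].is_nacp


def test_generated_topologies_validate(benzene_topology, hex_topology,
                                       h2_full_topology):
    for top in (benzene_topology, hex_topology, h2_full_topology):
        assert top.validate() == []


def test_ring_paths_terminate_at_ring_bcps(hf5_topology):
    g = hf5_topology.gvf
    ring_bcps = {g.molecular_graph.ails[ai].bcp for ai in g.rings[0].ails}
    assert len(g.ring_surfaces) == 1
    for p in g.ring_surfaces[0].paths:
        assert p.cp_end in ring_bcps


# ----------------------------------------------------------------------
# envelopes


def test_envelope_closed_form_hydrogen_like_atom():
    """For rho = (1/pi) e^(-2r), the 0.001-au envelope radius is
    ln(1/(0.001*pi))/2 ~ 2.8805 bohr in every direction."""
    nuc = Nucleus(element="H", position=np.zeros(3), index=0)
    den = PromolecularDensity([nuc], terms={"H": [(1.0 / math.pi, 2.0)]})
    cps = find_critical_points(den, seeds=np.empty((0, 3)))
    env = build_envelope(den, cps, 0, isovalue=0.001)
    radii = np.linalg.norm(env.mesh.vertices, axis=1)
    expected = math.log(1.0 / (0.001 * math.pi)) / 2.0  # ~2.8815 bohr
    np.testing.assert_allclose(radii, expected, atol=1e-6)


def test_envelope_vertices_on_isovalue(h2_full_topology):
    den = PromolecularDensity(h2_full_topology.nuclei)
    for env in h2_full_topology.gvf.envelopes:
        rho = den.rho(env.mesh.vertices)
        assert np.max(np.abs(rho - env.isovalue) / env.isovalue) < 1e-6


def test_envelope_is_watertight_sphere(h2_full_topology):
    import trimesh
    env = h2_full_topology.gvf.envelopes[0]
    assert env.mesh.euler_characteristic() == 2
    mesh = trimesh.Trimesh(vertices=env.mesh.vertices, faces=env.mesh.faces,
                           process=False)
    assert mesh.is_watertight


def test_envelope_isovalue_above_peak_rejected():
    nuc = Nucleus(element="H", position=np.zeros(3), index=0)
    den = PromolecularDensity([nuc], terms={"H": [(1.0, 2.0)]})
    cps = find_critical_points(den, seeds=np.empty((0, 3)))
    with pytest.raises(TopologyError):
        build_envelope(den, cps, 0, isovalue=10.0)


# ----------------------------------------------------------------------
# interatomic surfaces


def test_h2_ias_is_the_bisector_plane(h2_full_topology):
    """Mirror symmetry forces every IAS point to be equidistant from the
    two protons (within 1e-4 bohr)."""
    nuc = np.array([n.position for n in h2_full_topology.nuclei])
    surf = h2_full_topology.gvf.atomic_surfaces[0].interatomic_surfaces[0]
    for p in surf.paths:
        d0 = np.linalg.norm(p.points - nuc[0], axis=1)
        d1 = np.linalg.norm(p.points - nuc[1], axis=1)
        assert np.max(np.abs(d0 - d1)) < 1e-4


def test_h2_ias_separates_the_basins(h2_density):
    """Points offset either side of the IAS along the bond axis ascend to
    the two different nuclear attractors."""
    cps = find_critical_points(h2_density)
    ibcp = next(i for i, cp in enumerate(cps) if cp.is_bcp)
    axis = h2_density.centers[1] - h2_density.centers[0]
    axis /= np.linalg.norm(axis)
    for sign in (+1.0, -1.0):
        start = cps[ibcp].position + sign * 0.01 * axis
        path = trace_gradient_path(h2_density, start, sign * axis,
                                   "ascending", cps)
        end = cps[path.cp_end]
        assert end.is_nacp
        nearest = 1 if sign > 0 else 0
        np.testing.assert_allclose(end.position, h2_density.centers[nearest],
                                   atol=1e-10)


def test_hfh_anion_has_one_ias_per_bcp(hfh_ias_topology):
    census = hfh_ias_topology.census()
    assert census["BCP"] == 2
    all_ias = {ias.bcp
               for surf in hfh_ias_topology.gvf.atomic_surfaces
               for ias in surf.interatomic_surfaces}
    assert len(all_ias) == 2
    # the central fluorine is bounded by both surfaces
    f_surf = next(s for s in hfh_ias_topology.gvf.atomic_surfaces
                  if hfh_ias_topology.nuclei[s.nacp].element == "F")
    assert len(f_surf.interatomic_surfaces) == 2


def test_ias_requires_a_bond_cp(h2_density):
    cps = find_critical_points(h2_density)
    with pytest.raises(TopologyError):
        build_interatomic_surface(h2_density, cps, 0)  # an NACP


# ----------------------------------------------------------------------
# basins


def test_basin_paths_originate_at_their_nacp(hcn_topology):
    for basin in hcn_topology.gvf.basins:
        assert all(p.cp_start == basin.nacp for p in basin.paths)
        # most paths run to the density floor; bond-axis ones hit CPs
        ends = {p.cp_end for p in basin.paths}
        assert INFINITY in ends


def test_basin_fan_size(hcn_topology):
    for basin in hcn_topology.gvf.basins:
        assert len(basin.paths) == 162


def test_generation_options_control_components():
    top = generate_topology(build_fixture_geometry("h2"),
                            GenerationOptions(molecular_graph=False,
                                              rings=False, cages=False))
    assert top.gvf.molecular_graph.ails == []
    assert top.census()["BCP"] == 1  # CPs are always found
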