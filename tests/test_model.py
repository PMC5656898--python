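"""Topology model: CP classification, census arithmetic, assembly rules
and structural invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qctviz.model import (
    INFINITY,
    AtomicInteractionLine,
    Cage,
    CriticalPoint,
    GradientPath,
    MolecularGraph,
    Ring,
    RingSurface,
    Topology,
    TopologyError,
    Triangulation,
    assemble_molecular_graph,
    assemble_rings_and_cages,
    classify_critical_point,
    poincare_hopf_residual,
    topologies_allclose,
)


@pytest.mark.parametrize("eigenvalues, expected", [
    ((-2.0, -1.0, +5.0), (3, -1, "BCP")),
    ((-3.0, -1.5, -0.2), (3, -3, "NACP")),
    ((-1.0, 0.0, +1.0), (2, 0, "degenerate")),
    ((0.1, 0.2, 0.3), (3, 3, "CCP")),
    ((-0.1, 0.2, 0.3), (3, 1, "RCP")),
])
def test_classification_by_rank_and_signature(eigenvalues, expected):
    assert classify_critical_point(eigenvalues, zero_tol=1e-10) == expected


def test_classification_rejects_nonfinite_and_unsorted():
    with pytest.raises(TopologyError):
        classify_critical_point((np.nan, 0.0, 1.0))
    with pytest.raises(TopologyError):
        classify_critical_point((1.0, 0.0, -1.0))


@given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=3))
def test_classification_invariants(evs):
    """|signature| <= rank and signature == rank (mod 2) for any input."""
    rank, sig, label = classify_critical_point(sorted(evs), zero_tol=1e-8)
    assert 0 <= rank <= 3
    assert abs(sig) <= rank
    assert (sig - rank) % 2 == 0
    assert (label == "degenerate") == (rank < 3)


@pytest.mark.parametrize("counts, expected", [
    ((1, 0, 0, 0), 1),
    ((12, 12, 1, 0), 1),
    ((22, 24, 4, 1), 1),
    ((8, 8, 1, 0), 1),
])
def test_poincare_hopf_residual(counts, expected):
    assert poincare_hopf_residual(*counts) == expected


def test_poincare_hopf_rejects_negative_counts():
    with pytest.raises(TopologyError):
        poincare_hopf_residual(-1, 0, 0, 0)


def test_critical_point_rejects_illegal_signature():
    with pytest.raises(TopologyError):
        CriticalPoint(position=np.zeros(3), rank=3, signature=2)
    with pytest.raises(TopologyError):
        CriticalPoint(position=np.zeros(3), rank=2, signature=3)


def test_critical_point_checks_eigenvalue_consistency():
    with pytest.raises(TopologyError):
        CriticalPoint(position=np.zeros(3), rank=3, signature=-3,
                      eigenvalues=np.array([-1.0, -0.5, 2.0]))  # that's a BCP


def _cp(pos, sig):
    return CriticalPoint(position=np.asarray(pos, float), rank=3, signature=sig)


def _path(a, b, ia, ib):
    pts = np.linspace(a, b, 5)
    return GradientPath(points=pts, cp_start=ia, cp_end=ib)


def test_assemble_molecular_graph_pairs_paths():
    cps = [_cp([0, 0, 0], -3), _cp([2, 0, 0], -3), _cp([1, 0, 0], -1)]
    paths = [_path(np.array([1.0, 0, 0]), np.array([0.0, 0, 0]), 2, 0),
             _path(np.array([1.0, 0, 0]), np.array([2.0, 0, 0]), 2, 1)]
    graph = assemble_molecular_graph(paths, cps)
    assert len(graph.ails) == 1
    assert graph.ails[0].bcp == 2
    assert graph.ails[0].nacp_pair() == (0, 1)


def test_assemble_molecular_graph_empty():
    assert assemble_molecular_graph([], []).ails == []


def test_assemble_molecular_graph_skips_odd_bcp(caplog):
    cps = [_cp([0, 0, 0], -3), _cp([1, 0, 0], -1)]
    paths = [_path(np.array([1.0, 0, 0]), np.array([0.0, 0, 0]), 1, 0)]
    with caplog.at_level("WARNING"):
        graph = assemble_molecular_graph(paths, cps)
    assert graph.ails == []
    assert "expected 2" in caplog.text


def test_assemble_molecular_graph_ignores_infinity_paths():
    cps = [_cp([0, 0, 0], -3), _cp([1, 0, 0], -1)]
    paths = [_path(np.array([1.0, 0, 0]), np.array([0.0, 0, 0]), 1, 0),
             _path(np.array([1.0, 0, 0]), np.array([9.0, 0, 0]), 1, INFINITY)]
    assert assemble_molecular_graph(paths, cps).ails == []


def test_molecular_graph_rejects_duplicate_bcp():
    cps = [_cp([0, 0, 0], -3), _cp([2, 0, 0], -3), _cp([1, 0, 0], -1)]
    p1 = _path(np.array([1.0, 0, 0]), np.array([0.0, 0, 0]), 2, 0)
    p2 = _path(np.array([1.0, 0, 0]), np.array([2.0, 0, 0]), 2, 1)
    ail = AtomicInteractionLine(paths=[p1, p2], bcp=2)
    with pytest.raises(TopologyError):
        MolecularGraph(ails=[ail, ail])


def _triangle_fixture():
    """Three NACPs, three BCPs, one RCP in a triangle."""
    nac = [_cp([0, 0, 0], -3), _cp([2, 0, 0], -3), _cp([1, 2, 0], -3)]
    pos = [np.array(p.position) for p in nac]
    cps = list(nac)
    paths = []
    for (i, j) in [(0, 1), (1, 2), (0, 2)]:
        mid = 0.5 * (pos[i] + pos[j])
        cps.append(_cp(mid, -1))
        b = len(cps) - 1
        paths.append(_path(mid, pos[i], b, i))
        paths.append(_path(mid, pos[j], b, j))
    cps.append(_cp([1.0, 0.7, 0.0], +1))
    rcp = len(cps) - 1
    return cps, paths, rcp


def test_assemble_rings_requires_cycle_closure():
    cps, paths, rcp = _triangle_fixture()
    graph = assemble_molecular_graph(paths, cps)
    assert len(graph.ails) == 3
    ring_paths = [
        _path(np.array(cps[rcp].position), np.array(cps[b].position), rcp, b)
        for b in (3, 4, 5)]
    rings, cages = assemble_rings_and_cages(
        graph, [RingSurface(rcp=rcp, paths=ring_paths)], cps)
    assert len(rings) == 1
    assert rings[0].ails == [0, 1, 2]
    assert cages == []


def test_assemble_rings_omits_open_chains(caplog):
    cps, paths, rcp = _triangle_fixture()
    graph = assemble_molecular_graph(paths, cps)
    ring_paths = [
        _path(np.array(cps[rcp].position), np.array(cps[b].position), rcp, b)
        for b in (3, 4)]  # only 2 of 3 edges
    with caplog.at_level("WARNING"):
        rings, _ = assemble_rings_and_cages(
            graph, [RingSurface(rcp=rcp, paths=ring_paths)], cps)
    assert rings == []


def test_ring_and_cage_minimum_sizes():
    with pytest.raises(TopologyError):
        Ring(ails=[0, 1], rcp=0)
    with pytest.raises(TopologyError):
        Cage(rings=[0], ccp=0)


def test_gradient_path_rejects_degenerate_input():
    with pytest.raises(TopologyError):
        GradientPath(points=np.zeros((1, 3)), cp_start=0, cp_end=1)
    with pytest.raises(TopologyError):
        GradientPath(points=np.array([[0.0, 0, 0], [0.0, 0, 0]]),
                     cp_start=0, cp_end=1)


def test_triangulation_validation_and_euler():
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    tri = Triangulation(vertices=verts, faces=faces)
    assert tri.euler_characteristic() == 2  # tetrahedron is sphere-like
    with pytest.raises(TopologyError):
        Triangulation(vertices=verts, faces=np.array([[0, 1, 4]]))
    with pytest.raises(TopologyError):
        Triangulation(vertices=verts, faces=np.array([[0, 1, 1]]))


def test_topology_validate_flags_bad_references(hcn_topology):
    assert hcn_topology.validate() == []
    broken = Topology(source=hcn_topology.source,
                      nuclei=hcn_topology.nuclei,
                      critical_points=hcn_topology.critical_points[:2],
                      gvf=hcn_topology.gvf)
    assert any("does not resolve" in p for p in broken.validate())


def test_topologies_allclose_detects_perturbation(hcn_topology):
    assert topologies_allclose(hcn_topology, hcn_topology)
    import copy
    other = copy.deepcopy(hcn_topology)
    other.critical_points[0].position = other.critical_points[0].position + 1e-6
    assert not topologies_allclose(hcn_topology, other, atol=1e-9)
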