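"""Scene mapping: materials, object counts, curve smoothing, interaction
differentiation and AIL resizing."""

import io

import numpy as np
import pytest

from qctviz.export import export_scene_json
from qctviz.model import Topology, TopologyError
from qctviz.scene import (
    StyleOptions,
    default_materials,
    differentiate_interactions,
    map_topology,
    resize_ails,
    smooth_path,
)


def test_benzene_material_set(benzene_topology):
    """Two elements -> nucleus+surface each, plus the fixed
    bcp/rcp/ccp/ail quartet: 8 materials."""
    mats = default_materials(benzene_topology)
    names = {m.name for m in mats}
    assert names == {"C-nucleus", "C-surface", "H-nucleus", "H-surface",
                     "bcp", "rcp", "ccp", "ail"}
    for m in mats:
        assert m.specular_intensity == 0.5
        assert m.specular_rgb == (1.0, 1.0, 1.0)
        assert m.diffuse_intensity == 1.0
        assert m.diffuse_shader == "lambert"
        assert m.specular_shader == "cook-torrance"


def test_fixed_cp_materials_always_present(hcn_topology):
    names = {m.name for m in default_materials(hcn_topology)}
    assert {"bcp", "rcp", "ccp", "ail"} <= names
    assert "degenerate" not in names  # no degenerate CPs in this topology


def test_cp_material_colors(benzene_topology):
    mats = {m.name: m for m in default_materials(benzene_topology)}
    assert mats["bcp"].diffuse_rgb == (1.0, 0.0, 0.0)
    assert mats["rcp"].diffuse_rgb == (0.0, 0.0, 1.0)
    assert mats["ccp"].diffuse_rgb == (0.0, 1.0, 0.0)
    assert mats["ail"].diffuse_rgb == (0.0, 0.0, 0.0)
    assert mats["C-surface"].transparency == 0.6


def test_benzene_scene_object_counts(benzene_topology):
    """Census {12,12,1,0}: 25 CP spheres and 2 tubes per AIL -> 24."""
    scene = map_topology(benzene_topology, StyleOptions(show_ring_surfaces=False))
    spheres = [o for o in scene.objects if o.kind == "sphere"]
    tubes = [o for o in scene.objects if o.tag.startswith("ail:")]
    assert len(spheres) == 25
    assert len(tubes) == 24
    assert len(scene.objects) == 49


def test_empty_topology_scene_keeps_defaults():
    scene = map_topology(Topology())
    assert scene.objects == []
    assert scene.camera is not None
    assert len(scene.lights) == 3
    assert scene.render.width == 1000


def test_uniform_ail_style(benzene_topology):
    scene = map_topology(benzene_topology, StyleOptions(uniform_ail=True))
    tubes = [o for o in scene.objects if o.tag.startswith("ail:")]
    assert len(tubes) == 24
    assert all(o.material == "ail" for o in tubes)


def test_per_element_ail_coloring(benzene_topology):
    scene = map_topology(benzene_topology)
    tube_mats = {o.material for o in scene.objects if o.tag.startswith("ail:")}
    assert tube_mats == {"C-nucleus", "H-nucleus"}


def test_nacp_spheres_scale_with_vdw(benzene_topology):
    from qctviz.elements import vdw_radius_bohr
    scene = map_topology(benzene_topology)
    spheres = {o.tag: o for o in scene.objects if o.kind == "sphere"}
    carbon = spheres["cp:0"]
    assert carbon.radius == pytest.approx(0.25 * vdw_radius_bohr("C"))
    rcp_idx = benzene_topology.cp_indices("RCP")[0]
    assert spheres[f"cp:{rcp_idx}"].radius == pytest.approx(0.25)


def test_mapping_is_deterministic(benzene_topology):
    a, b = io.BytesIO(), io.BytesIO()
    export_scene_json(map_topology(benzene_topology), a)
    export_scene_json(map_topology(benzene_topology), b)
    assert a.getvalue() == b.getvalue()


# ----------------------------------------------------------------------
# smoothing


def test_smooth_collinear_stays_collinear():
    pts = np.outer(np.linspace(0, 5, 7), np.array([1.0, 2.0, -1.0]))
    out = smooth_path(pts)
    direction = pts[-1] / np.linalg.norm(pts[-1])
    cross = np.cross(out, direction)
    assert np.max(np.linalg.norm(cross, axis=1)) < 1e-9


def test_smooth_two_points_is_straight_segment():
    out = smooth_path(np.array([[0.0, 0, 0], [1.0, 1, 1]]))
    assert out.shape == (9, 3)  # 8 samples per segment + start
    np.testing.assert_allclose(out[0], [0, 0, 0])
    np.testing.assert_allclose(out[-1], [1, 1, 1])
    t = out[:, 0]
    np.testing.assert_allclose(out, np.outer(t, [1.0, 1, 1]), atol=1e-12)


def test_smooth_preserves_fixture_endpoints(hf5_topology):
    for ail in hf5_topology.gvf.molecular_graph.ails:
        for p in ail.paths:
            out = smooth_path(p.points)
            np.testing.assert_allclose(out[0], p.points[0], atol=0)
            np.testing.assert_allclose(out[-1], p.points[-1], atol=0)


def test_smooth_rejects_degenerate_input():
    with pytest.raises(TopologyError):
        smooth_path(np.array([[1.0, 1, 1], [1.0, 1, 1]]))


# ----------------------------------------------------------------------
# bonded / non-bonded differentiation


def test_hf_pentamer_differentiation(hf5_topology):
    """Five covalent F-H bonds, five F-H...F hydrogen bonds."""
    split = differentiate_interactions(
        hf5_topology.gvf.molecular_graph, hf5_topology, scale=0.6)
    assert len(split["bonded"]) == 5
    assert len(split["nonbonded"]) == 5


def test_h2_is_bonded(h2_full_topology):
    split = differentiate_interactions(
        h2_full_topology.gvf.molecular_graph, h2_full_topology)
    assert split == {"bonded": [0], "nonbonded": []}


def test_far_apart_ail_is_nonbonded():
    """A fabricated interaction between nuclei 6 A apart fails the vdW
    criterion."""
    import qctviz.model as m
    d = 6.0 * 1.8897259886
    cps = [m.CriticalPoint(position=np.array([0.0, 0, 0]), rank=3, signature=-3),
           m.CriticalPoint(position=np.array([d, 0, 0]), rank=3, signature=-3),
           m.CriticalPoint(position=np.array([d / 2, 0, 0]), rank=3, signature=-1)]
    nuclei = [m.Nucleus(element="C", position=cps[0].position, index=0),
              m.Nucleus(element="C", position=cps[1].position, index=1)]
    paths = [m.GradientPath(points=np.linspace(cps[2].position, cps[i].position, 4),
                            cp_start=2, cp_end=i) for i in (0, 1)]
    graph = m.assemble_molecular_graph(paths, cps)
    split = differentiate_interactions(graph, nuclei)
    assert split == {"bonded": [], "nonbonded": [0]}


def test_differentiate_style_thins_nonbonded_tubes(hf5_topology):
    style = StyleOptions(differentiate=True)
    scene = map_topology(hf5_topology, style)
    radii = sorted({o.radius for o in scene.objects if o.tag.startswith("ail:")})
    assert len(radii) == 2
    assert radii[0] == pytest.approx(style.nonbonded_ratio * radii[1])


# ----------------------------------------------------------------------
# resizing


def test_resize_identity_and_composition(benzene_topology):
    scene = map_topology(benzene_topology)
    same = resize_ails(scene, 1.0)
    twice_twice = resize_ails(resize_ails(scene, 2.0), 2.0)
    once_four = resize_ails(scene, 4.0)
    for a, b in ((same, scene), (twice_twice, once_four)):
        for oa, ob in zip(a.objects, b.objects):
            assert oa.radius == ob.radius


def test_resize_touches_only_ails(benzene_topology):
    scene = map_topology(benzene_topology)
    halved = resize_ails(scene, 0.5)
    for before, after in zip(scene.objects, halved.objects):
        if before.tag.startswith("ail:"):
            assert after.radius == pytest.approx(0.5 * before.radius)
        else:
            assert after.radius == before.radius
    with pytest.raises(TopologyError):
        resize_ails(scene, 0.0)
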