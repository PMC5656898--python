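"""Scene exports: canonical JSON determinism, mesh tessellation formulas
verified by an independent parser, glTF structure and the builder
script."""

import base64
import io
import json
from pathlib import Path

import numpy as np
import pytest
import trimesh

from qctviz.export import (
    emit_builder_script,
    export_mesh_scene,
    export_scene_json,
    tube_mesh,
    uv_sphere,
)
from qctviz.model import Topology, TopologyError
from qctviz.scene import SceneGraph, map_topology


@pytest.fixture(scope="module")
def benzene_scene(benzene_topology):
    return map_topology(benzene_topology)


def test_json_export_is_byte_identical(benzene_scene):
    a, b = io.BytesIO(), io.BytesIO()
    export_scene_json(benzene_scene, a)
    export_scene_json(benzene_scene, b)
    assert a.getvalue() == b.getvalue()


def test_empty_scene_json_has_defaults():
    buf = io.BytesIO()
    export_scene_json(map_topology(Topology()), buf)
    d = json.loads(buf.getvalue())
    assert d["objects"] == []
    assert d["render"]["width"] == 1000
    assert d["camera"] is not None
    assert len(d["lights"]) == 3


def test_benzene_scene_json_object_count(benzene_scene):
    buf = io.BytesIO()
    export_scene_json(benzene_scene, buf)
    d = json.loads(buf.getvalue())
    assert len(d["objects"]) == 49  # 25 spheres + 24 AIL tubes


def test_uv_sphere_vertex_count_formula():
    """32 x 16 UV-sphere: 32*(16-1) + 2 = 482 vertices."""
    v, f = uv_sphere(np.zeros(3), 1.0, segments=32, rings=16)
    assert len(v) == 482
    mesh = trimesh.Trimesh(vertices=v, faces=f, process=False)
    assert mesh.is_watertight
    np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)


def test_obj_reparse_matches_tessellation_formulas(tmp_path, h2_full_topology):
    """Round-trip oracle: vertex count re-parsed from the OBJ equals the
    sum of per-object closed-form tessellation counts."""
    scene = map_topology(h2_full_topology)
    path = tmp_path / "scene.obj"
    export_mesh_scene(scene, "obj", path)
    expected = 0
    for obj in scene.objects:
        if obj.kind == "sphere":
            expected += 32 * (16 - 1) + 2
        elif obj.kind == "curve":
            expected += 12 * len(obj.points)
        else:
            expected += len(obj.mesh.vertices)
    n_verts = sum(1 for line in path.read_text().splitlines()
                  if line.startswith("v "))
    assert n_verts == expected
    # independent parser agrees
    loaded = trimesh.load(path, process=False)
    total = (sum(len(g.vertices) for g in loaded.geometry.values())
             if hasattr(loaded, "geometry") else len(loaded.vertices))
    assert total == expected


def test_obj_writes_material_library(tmp_path, benzene_scene):
    path = tmp_path / "benzene.obj"
    export_mesh_scene(benzene_scene, "obj", path)
    mtl = (tmp_path / "benzene.mtl").read_text()
    for mat in benzene_scene.materials:
        assert f"newmtl {mat.name}\n" in mtl
    assert "mtllib benzene.mtl" in path.read_text()


def test_single_sphere_obj_vertex_count(tmp_path):
    from qctviz.scene import Material, SceneObject
    scene = SceneGraph(
        objects=[SceneObject(kind="sphere", material="m", tag="cp:0",
                             center=np.zeros(3), radius=1.0)],
        materials=[Material(name="m", diffuse_rgb=(1, 0, 0))])
    path = tmp_path / "s.obj"
    export_mesh_scene(scene, "obj", path)
    n = sum(1 for line in path.read_text().splitlines() if line.startswith("v "))
    assert n == 482


def test_ply_binary_roundtrip(tmp_path, benzene_scene):
    path = tmp_path / "benzene.ply"
    export_mesh_scene(benzene_scene, "ply", path)
    header = path.read_bytes()[:64]
    assert header.startswith(b"ply\nformat binary_little_endian 1.0\n")
    mesh = trimesh.load(path, process=False)
    expected = sum(
        482 if o.kind == "sphere" else 12 * len(o.points) if o.kind == "curve"
        else len(o.mesh.vertices) for o in benzene_scene.objects)
    assert len(mesh.vertices) == expected
    assert mesh.visual.vertex_colors is not None


def test_gltf_structure_and_materials(tmp_path, benzene_scene):
    path = tmp_path / "benzene.gltf"
    export_mesh_scene(benzene_scene, "gltf", path)
    doc = json.loads(path.read_text())
    assert doc["asset"]["version"] == "2.0"
    assert len(doc["meshes"]) == len(benzene_scene.objects)
    # specular intensity 0.5 maps to roughness 0.75
    for mat in doc["materials"]:
        assert mat["pbrMetallicRoughness"]["roughnessFactor"] == pytest.approx(0.75)
    # embedded buffer decodes and matches the declared length
    uri = doc["buffers"][0]["uri"]
    prefix = "data:application/octet-stream;base64,"
    blob = base64.b64decode(uri[len(prefix):])
    assert len(blob) == doc["buffers"][0]["byteLength"]
    loaded = trimesh.load(path, process=False)
    assert len(loaded.geometry) == len(benzene_scene.objects)


def test_empty_scene_mesh_exports(tmp_path):
    scene = map_topology(Topology())
    for fmt in ("obj", "ply", "gltf"):
        path = tmp_path / f"empty.{fmt}"
        export_mesh_scene(scene, fmt, path)
        assert path.exists() and path.stat().st_size > 0


def test_unsupported_format_rejected(tmp_path, benzene_scene):
    with pytest.raises(TopologyError, match="unsupported format"):
        export_mesh_scene(benzene_scene, "stl", tmp_path / "x.stl")


def test_exports_are_in_angstrom(tmp_path, h2_full_topology):
    """Sphere centers in the OBJ sit at the nuclear positions in A."""
    scene = map_topology(h2_full_topology)
    path = tmp_path / "h2.obj"
    export_mesh_scene(scene, "obj", path)
    verts = np.array([[float(x) for x in line.split()[1:4]]
                      for line in path.read_text().splitlines()
                      if line.startswith("v ")])
    # H2 spans ~0.37 A nuclei + ~2 A envelope; the bohr-scale span (~4.3)
    # would exceed this range
    assert 1.0 < np.abs(verts).max() < 4.0


def test_tube_mesh_vertex_layout():
    pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0.5, 0]])
    v, f = tube_mesh(pts, radius=0.1, sides=12)
    assert len(v) == 36
    assert len(f) == 2 * 12 * 2
    # ring radii equal the tube radius
    d0 = np.linalg.norm(v[:12] - pts[0], axis=1)
    np.testing.assert_allclose(d0, 0.1, atol=1e-12)


# ----------------------------------------------------------------------
# builder script


def test_builder_script_material_blocks(benzene_scene):
    buf = io.StringIO()
    emit_builder_script(benzene_scene, buf)
    text = buf.getvalue()
    for mat in benzene_scene.materials:
        assert text.count(f"MATERIALS[{mat.name!r}] = make_material(") == 1


def test_builder_script_object_statement_count(benzene_scene):
    buf = io.StringIO()
    emit_builder_script(benzene_scene, buf)
    text = buf.getvalue()
    assert text.count("\nadd_object(") == len(benzene_scene.objects)


def test_builder_script_is_deterministic(benzene_scene):
    a, b = io.StringIO(), io.StringIO()
    emit_builder_script(benzene_scene, a)
    emit_builder_script(benzene_scene, b)
    assert a.getvalue() == b.getvalue()


def test_builder_script_is_valid_python_text(tmp_path, benzene_scene):
    path = tmp_path / "builder.py"
    emit_builder_script(benzene_scene, path)
    compile(path.read_text(), str(path), "exec")  # syntax only; never run
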