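"""Scene serialization: canonical JSON, OBJ+MTL, PLY, glTF 2.0 and a
Blender-Python builder script.

All exports are pure functions of the scene graph: identical scenes
produce byte-identical files.  Mesh exports use a right-handed, +y-up
convention and convert lengths from bohr to angstrom (3D authoring tools
assume human-scale units).  Spheres are tessellated as UV-spheres
(default 32 segments x 16 rings), curves as open tube meshes (default
12-sided).
"""

from __future__ import annotations

import base64
import json
import math
import struct
from pathlib import Path

import numpy as np

from .model import TopologyError
from .scene import SceneGraph
from .units import ANGSTROM_PER_BOHR

DEFAULT_SPHERE_SEGMENTS = 32
DEFAULT_SPHERE_RINGS = 16
DEFAULT_TUBE_SIDES = 12


def _f(x) -> float:
    """Round to 12 significant digits for deterministic serialization."""
    return float(f"{float(x):.12g}")


def _vec(v):
    return [_f(x) for x in np.asarray(v, dtype=float).ravel()]


# ----------------------------------------------------------------------
# canonical scene JSON


def scene_to_dict(scene: SceneGraph) -> dict:
    """Deterministic plain-data description of a scene graph."""

    def camera_dict(cam):
        return None if cam is None else {
            "position": _vec(cam.position), "look_at": _vec(cam.look_at),
            "up": _vec(cam.up), "fov_deg": _f(cam.fov_deg)}

    objects = []
    for obj in scene.objects:
        rec = {"kind": obj.kind, "material": obj.material, "tag": obj.tag}
        if obj.kind == "sphere":
            rec["center"] = _vec(obj.center)
            rec["radius"] = _f(obj.radius)
        elif obj.kind == "curve":
            rec["points"] = [_vec(p) for p in obj.points]
            rec["radius"] = _f(obj.radius)
        else:
            rec["vertices"] = [_vec(v) for v in obj.mesh.vertices]
            rec["faces"] = [[int(i) for i in f] for f in obj.mesh.faces]
        objects.append(rec)
    materials = [{
        "name": m.name, "diffuse_rgb": _vec(m.diffuse_rgb),
        "diffuse_intensity": _f(m.diffuse_intensity),
        "specular_rgb": _vec(m.specular_rgb),
        "specular_intensity": _f(m.specular_intensity),
        "transparency": _f(m.transparency),
        "diffuse_shader": m.diffuse_shader,
        "specular_shader": m.specular_shader,
    } for m in scene.materials]
    lights = [{
        "kind": li.kind, "position": _vec(li.position),
        "aim": None if li.aim is None else _vec(li.aim),
        "energy": _f(li.energy), "color_rgb": _vec(li.color_rgb),
    } for li in scene.lights]
    r = scene.render
    render = {
        "width": r.width, "height": r.height,
        "antialias_samples": r.antialias_samples,
        "raytrace_samples": r.raytrace_samples,
        "output_format": r.output_format,
        "color_depth_bits": r.color_depth_bits,
        "compression": r.compression,
        "background_rgb": _vec(r.background_rgb)}
    return {
        "objects": objects,
        "materials": materials,
        "camera": camera_dict(scene.camera),
        "stereo_cameras": [camera_dict(c) for c in scene.stereo_cameras],
        "lights": lights,
        "render": render,
    }


def export_scene_json(scene: SceneGraph, destination) -> None:
    """Sorted-key JSON at 12 significant digits; identical scenes yield
    byte-identical files."""
    text = json.dumps(scene_to_dict(scene), sort_keys=True, indent=1)
    data = (text + "\n").encode("utf-8")
    if hasattr(destination, "write"):
        destination.write(data)
    else:
        with open(destination, "wb") as f:
            f.write(data)


# ----------------------------------------------------------------------
# tessellation


def uv_sphere(center, radius, segments=DEFAULT_SPHERE_SEGMENTS,
              rings=DEFAULT_SPHERE_RINGS):
    """UV-sphere mesh: segments*(rings-1) + 2 vertices."""
    cx, cy, cz = center
    verts = [(cx, cy + radius, cz)]  # north pole (+y up)
    for i in range(1, rings):
        phi = math.pi * i / rings
        for j in range(segments):
            th = 2.0 * math.pi * j / segments
            verts.append((cx + radius * math.sin(phi) * math.cos(th),
                          cy + radius * math.cos(phi),
                          cz + radius * math.sin(phi) * math.sin(th)))
    verts.append((cx, cy - radius, cz))  # south pole
    south = len(verts) - 1
    faces = []
    for j in range(segments):
        faces.append((0, 1 + (j + 1) % segments, 1 + j))
    for i in range(rings - 2):
        row0, row1 = 1 + i * segments, 1 + (i + 1) * segments
        for j in range(segments):
            a, b = row0 + j, row0 + (j + 1) % segments
            c, d = row1 + j, row1 + (j + 1) % segments
            faces.append((a, b, c))
            faces.append((b, d, c))
    last_row = 1 + (rings - 2) * segments
    for j in range(segments):
        faces.append((south, last_row + j, last_row + (j + 1) % segments))
    return np.array(verts), np.array(faces, dtype=int)


def tube_mesh(points, radius, sides=DEFAULT_TUBE_SIDES):
    """Open tube around a polyline using parallel-transport frames:
    sides * len(points) vertices."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise TopologyError("tube needs at least 2 points")
    tangents = np.empty_like(pts)
    tangents[0] = pts[1] - pts[0]
    tangents[-1] = pts[-1] - pts[-2]
    if n > 2:
        tangents[1:-1] = pts[2:] - pts[:-2]
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-300)
    # initial normal: anything perpendicular to the first tangent
    t0 = tangents[0]
    seed = np.array([0.0, 1.0, 0.0]) if abs(t0[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    normal = seed - np.dot(seed, t0) * t0
    normal /= np.linalg.norm(normal)
    verts = []
    angles = [2.0 * math.pi * k / sides for k in range(sides)]
    for i in range(n):
        if i > 0:  # transport the frame onto the new tangent
            normal = normal - np.dot(normal, tangents[i]) * tangents[i]
            nn = np.linalg.norm(normal)
            if nn < 1e-12:
                seed = np.array([1.0, 0.0, 0.0])
                normal = seed - np.dot(seed, tangents[i]) * tangents[i]
                nn = np.linalg.norm(normal)
            normal = normal / nn
        binormal = np.cross(tangents[i], normal)
        for a in angles:
            verts.append(pts[i] + radius * (math.cos(a) * normal
                                            + math.sin(a) * binormal))
    faces = []
    for i in range(n - 1):
        r0, r1 = i * sides, (i + 1) * sides
        for k in range(sides):
            a, b = r0 + k, r0 + (k + 1) % sides
            c, d = r1 + k, r1 + (k + 1) % sides
            faces.append((a, b, c))
            faces.append((b, d, c))
    return np.array(verts), np.array(faces, dtype=int)


def tessellate_scene(scene: SceneGraph,
                     sphere_segments=DEFAULT_SPHERE_SEGMENTS,
                     sphere_rings=DEFAULT_SPHERE_RINGS,
                     tube_sides=DEFAULT_TUBE_SIDES):
    """Yield (name, vertices_in_angstrom, faces, material) per object."""
    out = []
    for idx, obj in enumerate(scene.objects):
        if obj.kind == "sphere":
            v, f = uv_sphere(obj.center, obj.radius, sphere_segments, sphere_rings)
        elif obj.kind == "curve":
            v, f = tube_mesh(obj.points, obj.radius, tube_sides)
        else:
            v, f = np.asarray(obj.mesh.vertices, dtype=float), obj.mesh.faces
        name = obj.tag.replace(":", "_")
        out.append((f"{idx:04d}_{name}", v * ANGSTROM_PER_BOHR, f,
                    scene.material_by_name(obj.material)))
    return out


# ----------------------------------------------------------------------
# OBJ / PLY / glTF


def _export_obj(scene, destination, **tess):
    path = Path(destination)
    mtl_path = path.with_suffix(".mtl")
    parts = tessellate_scene(scene, **tess)
    with open(mtl_path, "w", encoding="utf-8", newline="\n") as m:
        m.write("# qctviz materials\n")
        for mat in scene.materials:
            m.write(f"newmtl {mat.name}\n")
            kd = [c * mat.diffuse_intensity for c in mat.diffuse_rgb]
            ks = [c * mat.specular_intensity for c in mat.specular_rgb]
            m.write(f"Kd {kd[0]:.6f} {kd[1]:.6f} {kd[2]:.6f}\n")
            m.write(f"Ks {ks[0]:.6f} {ks[1]:.6f} {ks[2]:.6f}\n")
            m.write(f"d {1.0 - mat.transparency:.6f}\n\n")
    with open(path, "w", encoding="utf-8", newline="\n") as o:
        o.write("# qctviz scene (angstrom, y-up, right-handed)\n")
        o.write(f"mtllib {mtl_path.name}\n")
        offset = 1
        for name, verts, faces, mat in parts:
            o.write(f"o {name}\n")
            o.write(f"usemtl {mat.name}\n")
            for v in verts:
                o.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in faces:
                o.write(f"f {f[0] + offset} {f[1] + offset} {f[2] + offset}\n")
            offset += len(verts)


def _export_ply(scene, destination, **tess):
    parts = tessellate_scene(scene, **tess)
    verts, faces, colors = [], [], []
    offset = 0
    for _, v, f, mat in parts:
        verts.append(v)
        faces.append(np.asarray(f, dtype=int) + offset)
        rgb = np.clip(np.array(mat.diffuse_rgb) * 255.0, 0, 255).astype(np.uint8)
        colors.append(np.tile(rgb, (len(v), 1)))
        offset += len(v)
    v = np.vstack(verts) if verts else np.empty((0, 3))
    f = np.vstack(faces) if faces else np.empty((0, 3), dtype=int)
    c = np.vstack(colors) if colors else np.empty((0, 3), dtype=np.uint8)
    header = (
        "ply\nformat binary_little_endian 1.0\n"
        "comment qctviz scene (angstrom, y-up, right-handed)\n"
        f"element vertex {len(v)}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        f"element face {len(f)}\n"
        "property list uchar int vertex_indices\nend_header\n")
    with open(destination, "wb") as out:
        out.write(header.encode("ascii"))
        for i in range(len(v)):
            out.write(struct.pack("<fffBBB", v[i, 0], v[i, 1], v[i, 2],
                                  c[i, 0], c[i, 1], c[i, 2]))
        for face in f:
            out.write(struct.pack("<Biii", 3, face[0], face[1], face[2]))


def _export_gltf(scene, destination, **tess):
    parts = tessellate_scene(scene, **tess)
    mat_names = [m.name for m in scene.materials]
    materials = []
    for m in scene.materials:
        materials.append({
            "name": m.name,
            "pbrMetallicRoughness": {
                "baseColorFactor": [*map(_f, m.diffuse_rgb),
                                    _f(1.0 - m.transparency)],
                "metallicFactor": 0.0,
                "roughnessFactor": _f(1.0 - 0.5 * m.specular_intensity),
            },
            **({"alphaMode": "BLEND"} if m.transparency > 0 else {}),
        })
    buffer = bytearray()
    buffer_views, accessors, meshes, nodes = [], [], [], []
    for name, verts, faces, mat in parts:
        v32 = np.ascontiguousarray(verts, dtype="<f4")
        i32 = np.ascontiguousarray(np.asarray(faces, dtype="<u4").ravel())
        vb_off = len(buffer)
        buffer.extend(v32.tobytes())
        ib_off = len(buffer)
        buffer.extend(i32.tobytes())
        while len(buffer) % 4:
            buffer.append(0)
        buffer_views.append({"buffer": 0, "byteOffset": vb_off,
                             "byteLength": v32.nbytes, "target": 34962})
        buffer_views.append({"buffer": 0, "byteOffset": ib_off,
                             "byteLength": i32.nbytes, "target": 34963})
        vi, ii = len(buffer_views) - 2, len(buffer_views) - 1
        accessors.append({
            "bufferView": vi, "componentType": 5126, "count": len(v32),
            "type": "VEC3",
            "min": [_f(x) for x in v32.min(axis=0)] if len(v32) else [0, 0, 0],
            "max": [_f(x) for x in v32.max(axis=0)] if len(v32) else [0, 0, 0]})
        accessors.append({"bufferView": ii, "componentType": 5125,
                          "count": int(i32.size), "type": "SCALAR"})
        ai, aj = len(accessors) - 2, len(accessors) - 1
        meshes.append({"name": name, "primitives": [{
            "attributes": {"POSITION": ai}, "indices": aj,
            "material": mat_names.index(mat.name)}]})
        nodes.append({"name": name, "mesh": len(meshes) - 1})
    doc = {
        "asset": {"version": "2.0", "generator": "qctviz"},
        "scene": 0,
        "scenes": [{"nodes": list(range(len(nodes)))}],
        "nodes": nodes,
        "meshes": meshes,
        "materials": materials,
        "accessors": accessors,
        "bufferViews": buffer_views,
        "buffers": [{
            "byteLength": len(buffer),
            "uri": "data:application/octet-stream;base64,"
                   + base64.b64encode(bytes(buffer)).decode("ascii")}],
    }
    for key in ("nodes", "meshes", "accessors", "bufferViews"):
        if not doc[key]:
            del doc[key]
    if not materials:
        del doc["materials"]
    data = json.dumps(doc, sort_keys=True, indent=1).encode("utf-8")
    with open(destination, "wb") as f:
        f.write(data)


_EXPORTERS = {"obj": _export_obj, "ply": _export_ply, "gltf": _export_gltf}


def export_mesh_scene(scene: SceneGraph, fmt: str, destination, **tess) -> None:
    """Export the tessellated scene to OBJ (+MTL), binary PLY, or glTF 2.0."""
    try:
        exporter = _EXPORTERS[fmt]
    except KeyError:
        raise TopologyError(
            f"unsupported format {fmt!r}; choose from {sorted(_EXPORTERS)}"
        ) from None
    exporter(scene, destination, **tess)


# ----------------------------------------------------------------------
# builder script


def emit_builder_script(scene: SceneGraph, destination) -> None:
    """Write a standalone Blender-Python script that recreates the scene
    (objects, materials, camera, lights, render settings).

    The script is plain text and is never executed by this toolkit.
    """
    d = scene_to_dict(scene)
    lines = [
        "# Auto-generated scene builder script (Blender Python API).",
        "# Recreates the scene graph: materials, objects, camera, lights,",
        "# render settings.  Lengths in angstrom.",
        "import bpy, json",
        "",
        f"SCENE = json.loads('''{json.dumps(d, sort_keys=True)}''')",
        "",
        "SCALE = 0.529177210903  # bohr -> angstrom",
        "",
        "def make_material(spec):",
        "    mat = bpy.data.materials.new(spec['name'])",
        "    mat.use_nodes = True",
        "    bsdf = mat.node_tree.nodes['Principled BSDF']",
        "    bsdf.inputs['Base Color'].default_value = "
        "(*spec['diffuse_rgb'], 1.0)",
        "    bsdf.inputs['Roughness'].default_value = "
        "1.0 - 0.5 * spec['specular_intensity']",
        "    bsdf.inputs['Alpha'].default_value = 1.0 - spec['transparency']",
        "    return mat",
        "",
        "MATERIALS = {}",
    ]
    for m in scene.materials:
        lines.append(
            f"MATERIALS[{m.name!r}] = make_material("
            f"[s for s in SCENE['materials'] if s['name'] == {m.name!r}][0])")
    lines += [
        "",
        "def add_object(spec):",
        "    if spec['kind'] == 'sphere':",
        "        bpy.ops.mesh.primitive_uv_sphere_add(",
        "            radius=spec['radius'] * SCALE,",
        "            location=[c * SCALE for c in spec['center']])",
        "    elif spec['kind'] == 'curve':",
        "        cu = bpy.data.curves.new(spec['tag'], 'CURVE')",
        "        cu.dimensions = '3D'",
        "        cu.bevel_depth = spec['radius'] * SCALE",
        "        sp = cu.splines.new('POLY')",
        "        sp.points.add(len(spec['points']) - 1)",
        "        for pt, xyz in zip(sp.points, spec['points']):",
        "            pt.co = (*[c * SCALE for c in xyz], 1.0)",
        "        ob = bpy.data.objects.new(spec['tag'], cu)",
        "        bpy.context.collection.objects.link(ob)",
        "        ob.data.materials.append(MATERIALS[spec['material']])",
        "        return",
        "    else:",
        "        me = bpy.data.meshes.new(spec['tag'])",
        "        me.from_pydata([[c * SCALE for c in v]",
        "                        for v in spec['vertices']], [], spec['faces'])",
        "        ob = bpy.data.objects.new(spec['tag'], me)",
        "        bpy.context.collection.objects.link(ob)",
        "        ob.data.materials.append(MATERIALS[spec['material']])",
        "        return",
        "    ob = bpy.context.active_object",
        "    ob.name = spec['tag']",
        "    ob.data.materials.append(MATERIALS[spec['material']])",
        "",
    ]
    for obj in scene.objects:
        lines.append(f"add_object([s for s in SCENE['objects'] "
                     f"if s['tag'] == {obj.tag!r}][0])")
    lines += [
        "",
        "cam_spec = SCENE['camera']",
        "if cam_spec is not None:",
        "    cam_data = bpy.data.cameras.new('camera')",
        "    cam = bpy.data.objects.new('camera', cam_data)",
        "    bpy.context.collection.objects.link(cam)",
        "    cam.location = [c * SCALE for c in cam_spec['position']]",
        "for li in SCENE['lights']:",
        "    kind = 'SPOT' if li['kind'] == 'spot' else 'POINT'",
        "    ld = bpy.data.lights.new(li['kind'], kind)",
        "    ld.energy = li['energy']",
        "    lo = bpy.data.objects.new(li['kind'], ld)",
        "    bpy.context.collection.objects.link(lo)",
        "    lo.location = [c * SCALE for c in li['position']]",
        "r = SCENE['render']",
        "bpy.context.scene.render.resolution_x = r['width']",
        "bpy.context.scene.render.resolution_y = r['height']",
        "bpy.context.scene.render.image_settings.file_format = "
        "r['output_format'].upper()",
        "bpy.context.scene.render.image_settings.color_depth = "
        "str(r['color_depth_bits'])",
        "",
    ]
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="utf-8", newline="\n") as f:
            f.write(text)
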