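"""Canonical mapping from a topology to a renderer-agnostic scene graph.

Critical points become spheres (nuclear attractors sized by a fraction of
their element's van der Waals radius, all other CPs a small fixed
radius), gradient paths become smoothed tube curves, and surface or
envelope triangulations become meshes.  Default materials use a Lambert
diffuse shader (intensity 1.0) and a white Cook-Torrance specular shader
(intensity 0.5); nucleus and surface colors follow the PyMOL element
palette, bond/ring/cage CPs are red/blue/green, interaction lines black.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .elements import element_color, vdw_radius_bohr
from .model import SNAP_TOL, Topology, TopologyError, Triangulation
from .staging import (
    Camera,
    Light,
    RenderSettings,
    SceneFrame,
    compute_frame,
    default_render_settings,
    place_camera,
    place_lights,
)

log = logging.getLogger(__name__)

#: CP sphere color palettes (BCP, RCP, CCP) offered by existing QCT
#: viewers; the implementation default is red/blue/green.
CP_PALETTES = {
    "default": {"bcp": (1.0, 0.0, 0.0), "rcp": (0.0, 0.0, 1.0),
                "ccp": (0.0, 1.0, 0.0)},
    "morphy": {"bcp": (0.63, 0.13, 0.94), "rcp": (1.0, 0.75, 0.80),
               "ccp": (1.0, 0.0, 0.0)},
    "aimstudio": {"bcp": (0.0, 1.0, 0.0), "rcp": (1.0, 0.0, 0.0),
                  "ccp": (0.0, 0.0, 1.0)},
}

DEGENERATE_COLOR = (1.0, 0.0, 1.0)  # magenta; any color distinct from rank-3 CPs


@dataclass
class Material:
    name: str
    diffuse_rgb: tuple
    diffuse_intensity: float = 1.0
    specular_rgb: tuple = (1.0, 1.0, 1.0)
    specular_intensity: float = 0.5
    transparency: float = 0.0
    diffuse_shader: str = "lambert"
    specular_shader: str = "cook-torrance"

    def __post_init__(self):
        if self.diffuse_intensity < 0 or self.specular_intensity < 0:
            raise TopologyError("material intensities must be >= 0")
        if not 0.0 <= self.transparency <= 1.0:
            raise TopologyError("transparency must be in [0, 1]")


@dataclass
class SceneObject:
    kind: str               # "sphere" | "curve" | "mesh"
    material: str
    tag: str                # provenance, e.g. "cp:3", "ail:2:1", "envelope:0"
    center: np.ndarray | None = None
    radius: float | None = None           # sphere radius or tube radius
    points: np.ndarray | None = None      # sampled curve control points
    mesh: Triangulation | None = None

    def __post_init__(self):
        if self.kind not in ("sphere", "curve", "mesh"):
            raise TopologyError(f"unknown scene-object kind {self.kind!r}")
        if self.kind in ("sphere", "curve"):
            if self.radius is None or not self.radius > 0:
                raise TopologyError(f"{self.kind} needs a positive radius")


@dataclass
class SceneGraph:
    objects: list = field(default_factory=list)
    materials: list = field(default_factory=list)
    camera: Camera | None = None
    lights: list = field(default_factory=list)
    render: RenderSettings = field(default_factory=default_render_settings)
    stereo_cameras: list = field(default_factory=list)
    frame: SceneFrame | None = None

    @property
    def background_rgb(self) -> tuple:
        return self.render.background_rgb

    def material_by_name(self, name: str) -> Material:
        for m in self.materials:
            if m.name == name:
                return m
        raise KeyError(name)

    def check(self) -> None:
        names = {m.name for m in self.materials}
        for obj in self.objects:
            if obj.material not in names:
                raise TopologyError(
                    f"object {obj.tag} references unknown material {obj.material!r}")


@dataclass
class StyleOptions:
    """Presentation knobs; all defaults overridable via config or CLI."""

    vdw_scale: float = 0.25        # NACP sphere = vdw_scale * vdW radius
    cp_radius: float = 0.25        # bohr; all non-NACP CP spheres
    ail_radius: float = 0.1        # bohr; bonded AIL tube radius
    thin_radius: float = 0.05      # bohr; basin / ring-surface tubes
    nonbonded_ratio: float = 0.25  # nonbonded AIL radius / bonded radius
    uniform_ail: bool = False      # single black AIL material
    differentiate: bool = False    # thin out non-bonded interactions
    vdw_bond_scale: float = 0.6    # bonded iff d <= scale*(vdwA+vdwB)
    surface_transparency: float = 0.6
    show_basins: bool = True
    show_ring_surfaces: bool = False
    show_rings: bool = False
    show_cages: bool = False
    palette: str = "default"
    stereo: bool = False
    stereo_half_angle: float = 2.0


# ----------------------------------------------------------------------
# materials


def default_materials(topology: Topology, style: StyleOptions | None = None) -> list:
    """One nucleus + one surface material per unique element, the fixed
    bcp/rcp/ccp/ail set, and a degenerate-CP material when needed."""
    style = style or StyleOptions()
    palette = CP_PALETTES[style.palette]
    materials = []
    elements = sorted({n.element for n in topology.nuclei})
    for el in elements:
        rgb = element_color(el)
        materials.append(Material(name=f"{el}-nucleus", diffuse_rgb=rgb))
        materials.append(Material(name=f"{el}-surface", diffuse_rgb=rgb,
                                  transparency=style.surface_transparency))
    materials.append(Material(name="bcp", diffuse_rgb=palette["bcp"]))
    materials.append(Material(name="rcp", diffuse_rgb=palette["rcp"]))
    materials.append(Material(name="ccp", diffuse_rgb=palette["ccp"]))
    materials.append(Material(name="ail", diffuse_rgb=(0.0, 0.0, 0.0)))
    if any(cp.label == "degenerate" for cp in topology.critical_points):
        materials.append(Material(name="degenerate", diffuse_rgb=DEGENERATE_COLOR))
    return materials


# ----------------------------------------------------------------------
# curve smoothing


def smooth_path(points: np.ndarray, samples_per_segment: int = 8) -> np.ndarray:
    """Smooth a polyline into a Catmull-Rom chain of cubic Bezier
    segments (tension 0.5) and sample it back for tessellation.

    Endpoints are interpolated exactly; duplicate consecutive input
    points are removed first.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts):
        keep = np.concatenate([[True],
                               np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0.0])
        pts = pts[keep]
    if len(pts) < 2:
        raise TopologyError("need at least 2 distinct points to smooth")
    n = len(pts)
    # one-sided tangents at the ends, central differences inside
    tangents = np.empty_like(pts)
    tangents[0] = pts[1] - pts[0]
    tangents[-1] = pts[-1] - pts[-2]
    if n > 2:
        tangents[1:-1] = 0.5 * (pts[2:] - pts[:-2])
    out = [pts[0]]
    ts = np.linspace(0.0, 1.0, samples_per_segment + 1)[1:]
    for i in range(n - 1):
        p0, p1 = pts[i], pts[i + 1]
        c0 = p0 + tangents[i] / 3.0
        c1 = p1 - tangents[i + 1] / 3.0
        for t in ts:
            u = 1.0 - t
            out.append(u ** 3 * p0 + 3 * u ** 2 * t * c0
                       + 3 * u * t ** 2 * c1 + t ** 3 * p1)
    out = np.array(out)
    out[-1] = pts[-1]  # exact endpoint despite rounding
    return out


# ----------------------------------------------------------------------
# interaction differentiation


def _nacp_to_nucleus(topology: Topology) -> dict:
    """Map NACP index -> Nucleus via the snap-tolerance identity."""
    mapping = {}
    for i, cp in enumerate(topology.critical_points):
        if not cp.is_nacp:
            continue
        for nuc in topology.nuclei:
            if np.linalg.norm(nuc.position - cp.position) <= SNAP_TOL:
                mapping[i] = nuc
                break
    return mapping


def differentiate_interactions(graph, nuclei_or_topology, scale: float = 0.6) -> dict:
    """Partition AIL indices into bonded / nonbonded by the van der Waals
    criterion: bonded iff the internuclear distance does not exceed
    ``scale * (vdw_A + vdw_B)``."""
    if isinstance(nuclei_or_topology, Topology):
        topology = nuclei_or_topology
    else:
        topology = Topology(nuclei=list(nuclei_or_topology), critical_points=[])
    if isinstance(nuclei_or_topology, Topology):
        n_map = _nacp_to_nucleus(topology)
    else:
        n_map = {n.index: n for n in topology.nuclei}
    out = {"bonded": [], "nonbonded": []}
    for i, ail in enumerate(graph.ails):
        a, b = ail.nacp_pair()
        na, nb = n_map.get(a), n_map.get(b)
        if na is None or nb is None:
            log.warning("AIL %d endpoints do not map to nuclei; counted bonded", i)
            out["bonded"].append(i)
            continue
        d = np.linalg.norm(na.position - nb.position)
        limit = scale * (vdw_radius_bohr(na.element) + vdw_radius_bohr(nb.element))
        out["bonded" if d <= limit else "nonbonded"].append(i)
    return out


# ----------------------------------------------------------------------
# mapping


def map_topology(topology: Topology, style: StyleOptions | None = None) -> SceneGraph:
    """Build the scene graph for a topology under the given style."""
    style = style or StyleOptions()
    scene = SceneGraph()
    scene.materials = default_materials(topology, style)
    n_map = _nacp_to_nucleus(topology)

    for i, cp in enumerate(topology.critical_points):
        if cp.is_nacp:
            nuc = n_map.get(i)
            if nuc is None:
                log.warning("NACP %d has no coincident nucleus; fixed radius", i)
                radius, mat = style.cp_radius, "bcp"
            else:
                radius = style.vdw_scale * vdw_radius_bohr(nuc.element)
                mat = f"{nuc.element}-nucleus"
        else:
            radius = style.cp_radius
            mat = {"BCP": "bcp", "RCP": "rcp", "CCP": "ccp",
                   "degenerate": "degenerate"}[cp.label]
        scene.objects.append(SceneObject(
            kind="sphere", material=mat, tag=f"cp:{i}",
            center=cp.position.copy(), radius=radius))

    graph = topology.gvf.molecular_graph
    nonbonded = set()
    if style.differentiate:
        nonbonded = set(differentiate_interactions(
            graph, topology, style.vdw_bond_scale)["nonbonded"])
    for j, ail in enumerate(graph.ails):
        radius = style.ail_radius
        if j in nonbonded:
            radius *= style.nonbonded_ratio
        for k, path in enumerate(ail.paths):
            if style.uniform_ail:
                mat = "ail"
            else:
                far = path.cp_end if path.cp_start == ail.bcp else path.cp_start
                nuc = n_map.get(far)
                mat = f"{nuc.element}-nucleus" if nuc is not None else "ail"
            scene.objects.append(SceneObject(
                kind="curve", material=mat, tag=f"ail:{j}:{k}",
                points=smooth_path(path.points), radius=radius))

    if style.show_ring_surfaces or style.show_rings:
        for m, rs in enumerate(topology.gvf.ring_surfaces):
            for k, path in enumerate(rs.paths):
                scene.objects.append(SceneObject(
                    kind="curve", material="rcp", tag=f"ring-path:{m}:{k}",
                    points=smooth_path(path.points), radius=style.thin_radius))

    if style.show_basins:
        for m, basin in enumerate(topology.gvf.basins):
            for k, path in enumerate(basin.paths):
                scene.objects.append(SceneObject(
                    kind="curve", material="ail", tag=f"basin-path:{m}:{k}",
                    points=smooth_path(path.points), radius=style.thin_radius))

    for m, surf in enumerate(topology.gvf.atomic_surfaces):
        nuc = n_map.get(surf.nacp)
        mat = f"{nuc.element}-surface" if nuc is not None else "bcp"
        for k, ias in enumerate(surf.interatomic_surfaces):
            if ias.mesh is not None:
                scene.objects.append(SceneObject(
                    kind="mesh", material=mat, tag=f"ias:{m}:{k}", mesh=ias.mesh))
    for m, env in enumerate(topology.gvf.envelopes):
        nuc = n_map.get(env.nacp)
        mat = f"{nuc.element}-surface" if nuc is not None else "bcp"
        scene.objects.append(SceneObject(
            kind="mesh", material=mat, tag=f"envelope:{m}", mesh=env.mesh))

    if topology.critical_points:
        frame = compute_frame(topology.critical_points)
    else:
        frame = SceneFrame(center=np.zeros(3), extent=1.0)
    scene.frame = frame
    scene.camera = place_camera(frame)
    scene.lights = place_lights(frame, scene.camera)
    scene.render = default_render_settings()
    if style.stereo:
        from .staging import make_stereo_pair
        scene.stereo_cameras = list(make_stereo_pair(
            scene.camera, frame, style.stereo_half_angle))
    scene.check()
    return scene


def resize_ails(scene: SceneGraph, factor: float) -> SceneGraph:
    """Scale every AIL tube radius by `factor`; everything else untouched."""
    if not factor > 0:
        raise TopologyError("resize factor must be positive")
    out = replace(scene, objects=[
        replace(obj, radius=obj.radius * factor)
        if obj.tag.startswith("ail:") else obj
        for obj in scene.objects])
    return out
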