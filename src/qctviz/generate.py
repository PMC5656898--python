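"""Full synthetic-topology pipeline on a promolecular density.

``generate_topology`` emulates the output of a quantum-chemical-topology
analysis program at desk scale: it locates and classifies all critical
points, builds each bond CP's atomic interaction line, assembles the
molecular graph, rings and cages, and (optionally) basin path fans,
interatomic surfaces and constant-density envelopes.

Ring construction.  The unstable manifold of a ring CP (its "ring
surface") is spanned by the two positive Hessian eigendirections.  A fan
of ascending gradient paths is seeded in that eigenplane; generic fan
paths climb to nuclear attractors, while the separatrix paths that end at
the ring's bond CPs lie between fan neighbours reaching *different*
attractors.  Each such bracket is refined by bisection on the seed angle
until the traced path terminates at a BCP.  The set of AILs whose BCPs
are reached this way is accepted as a ring only if it closes into a
single cycle over the nuclear attractors.

Cage construction.  A cage CP is a local minimum, so descending paths
*from* it do not exist; instead each ring CP is traced descending along
its single negative eigendirection (both senses).  A ring belongs to a
cage iff one of these traces terminates at the cage's CP.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import trimesh

from .density import PromolecularDensity
from .fixtures import FixtureGeometry
from .model import (
    AtomicBasin,
    AtomicSurface,
    Envelope,
    GradientVectorField,
    InteratomicSurface,
    RingSurface,
    SourceInformation,
    Topology,
    Triangulation,
    TopologyError,
    assemble_molecular_graph,
    assemble_rings_and_cages,
)
from .search import TracingError, find_critical_points, trace_gradient_path

log = logging.getLogger(__name__)


@dataclass
class GenerationOptions:
    """Knobs of the synthetic-topology pipeline.

    The molecular graph, rings and cages are generated by default; basin
    fans, interatomic surfaces and envelopes are opt-in since they
    dominate run time and most molecular-graph figures do not need them.
    """

    molecular_graph: bool = True
    rings: bool = True
    cages: bool = True
    basins: bool = False
    interatomic_surfaces: bool = False
    envelopes: bool = False

    rho_floor: float = 1e-4          # au; path truncation threshold
    envelope_isovalue: float = 0.001  # au; conventional outer envelope
    envelope_subdivision: int = 3     # icosphere level (3 -> 642 vertices)
    basin_directions: int = 162       # icosahedral fan size per NACP
    ring_fan: int = 64                # ascending seeds per RCP
    ias_angular: int = 36             # angular seeds per IAS
    ias_rings: int = 8                # seed rings per IAS
    trace_step: float = 0.05          # bohr; RK4 arc-length step


def _eigvec(cp, which: int) -> np.ndarray:
    if cp.eigenvectors is None:
        raise TopologyError("CP carries no eigen-system")
    return cp.eigenvectors[which]


def icosphere_directions(subdivisions: int) -> np.ndarray:
    """Unit directions from an icosahedral subdivision (level 2 -> 162)."""
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(mesh.vertices, dtype=float)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# ----------------------------------------------------------------------
# component builders


def build_ails(density, cps, opts: GenerationOptions) -> list:
    """Two ascending paths along +-lambda3 for every bond CP."""
    paths = []
    for i, cp in enumerate(cps):
        if not cp.is_bcp:
            continue
        v3 = _eigvec(cp, 2)
        for sgn in (+1.0, -1.0):
            try:
                paths.append(trace_gradient_path(
                    density, cp.position, sgn * v3, "ascending", cps,
                    step=opts.trace_step, rho_floor=opts.rho_floor, cp_start=i))
            except TracingError as exc:
                log.warning("BCP %d bond-path trace failed: %s", i, exc)
    return paths


def build_ring_surface(density, cps, rcp_index: int, opts: GenerationOptions,
                       max_bisect: int = 60, capture_tol: float = 0.02,
                       seed_radius: float = 0.3) -> RingSurface:
    """Separatrix ring paths RCP -> BCP via angular bisection of an
    ascending fan in the lambda2-lambda3 eigenplane.

    A saddle passage amplifies the seed-angle offset by a power law, so a
    bisected path approaches the target BCP only polynomially fast; the
    traces therefore use a dedicated CP capture radius ``capture_tol``
    (well below interatomic distances, above the float64 amplification
    floor), with the endpoint snapped exactly onto the captured CP, and
    seeds are placed at ``seed_radius`` from the RCP so the bisected
    angle keeps its resolution instead of spending it on the slow escape
    from the near-degenerate RCP region.
    """
    cp = cps[rcp_index]
    v2, v3 = _eigvec(cp, 1), _eigvec(cp, 2)

    def trace_at(theta):
        d = math.cos(theta) * v2 + math.sin(theta) * v3
        return trace_gradient_path(
            density, cp.position, d, "ascending", cps,
            step=opts.trace_step, rho_floor=opts.rho_floor,
            snap_tol=capture_tol, seed_offset=seed_radius, cp_start=rcp_index)

    n = opts.ring_fan
    thetas = 2.0 * math.pi * np.arange(n) / n
    fan, ends = [], []
    for th in thetas:
        try:
            p = trace_at(th)
        except TracingError as exc:
            log.warning("RCP %d fan trace failed: %s", rcp_index, exc)
            p = None
        fan.append(p)
        ends.append(None if p is None else p.cp_end)

    bcp_idx = np.array([i for i, c in enumerate(cps) if c.is_bcp], dtype=int)
    bcp_pos = np.array([cps[i].position for i in bcp_idx]).reshape(-1, 3)

    def closest_bcp(path):
        d = np.linalg.norm(path.points[:, None, :] - bcp_pos[None], axis=2)
        flat = int(d.argmin())
        return flat // d.shape[1], flat % d.shape[1], float(d.min())

    kept = {}
    # fan paths that already terminate at a BCP
    for p in fan:
        if p is not None and 0 <= p.cp_end < len(cps) and cps[p.cp_end].is_bcp:
            kept.setdefault(p.cp_end, p)
    # bisect every bracket of distinct non-BCP terminations; a new
    # attractor surfacing inside a bracket (a basin sliver that the fan
    # resolution missed) splits the bracket so both of its bounding
    # separatrices are refined
    work = []
    for k in range(n):
        ta, tb = ends[k], ends[(k + 1) % n]
        if ta is None or tb is None or ta == tb:
            continue
        if (0 <= ta < len(cps) and cps[ta].is_bcp) or \
           (0 <= tb < len(cps) and cps[tb].is_bcp):
            continue
        work.append((thetas[k], ta, thetas[k] + 2.0 * math.pi / n, tb))
    budget = 8 * n  # safety cap on total brackets processed
    while work and budget > 0:
        budget -= 1
        lo, ta, hi, tb = work.pop()
        found, best = None, None
        for _ in range(max_bisect):
            if hi - lo <= 1e-15:  # float64 angle resolution exhausted
                break
            mid = 0.5 * (lo + hi)
            try:
                p = trace_at(mid)
            except TracingError:
                break
            e = p.cp_end
            if 0 <= e < len(cps) and cps[e].is_bcp:
                found = p
                break
            if best is None or closest_bcp(p)[2] < best[1]:
                best = (p, closest_bcp(p)[2])
            if e == ta:
                lo = mid
            elif e == tb:
                hi = mid
            else:
                work.append((lo, ta, mid, e))
                lo, ta = mid, e
        if found is None and best is not None:
            # bisection saturated short of capture_tol: accept the best
            # near-miss if it is unambiguously close to one BCP, truncating
            # at the closest approach and snapping onto the BCP.
            p, dmin = best
            if dmin <= 5.0 * capture_tol:
                ipt, jb, _ = closest_bcp(p)
                bcp = int(bcp_idx[jb])
                pts = np.vstack([p.points[:max(ipt, 1) + 1], cps[bcp].position])
                rho = density.rho(pts)
                found = type(p)(points=pts, cp_start=p.cp_start, cp_end=bcp,
                                scalars={"rho": rho})
        if found is not None:
            kept.setdefault(found.cp_end, found)
    return RingSurface(rcp=rcp_index, paths=[kept[b] for b in sorted(kept)])


def link_cages(density, cps, opts: GenerationOptions) -> dict:
    """Map CCP index -> set of RCP indices whose descending lambda1
    traces terminate at it."""
    links: dict = {}
    for i, cp in enumerate(cps):
        if not cp.is_rcp:
            continue
        v1 = _eigvec(cp, 0)
        for sgn in (+1.0, -1.0):
            try:
                p = trace_gradient_path(
                    density, cp.position, sgn * v1, "descending", cps,
                    step=opts.trace_step, rho_floor=opts.rho_floor, cp_start=i)
            except TracingError as exc:
                log.warning("RCP %d cage-link trace failed: %s", i, exc)
                continue
            e = p.cp_end
            if 0 <= e < len(cps) and cps[e].is_ccp:
                links.setdefault(e, set()).add(i)
    return links


def build_basin(density, cps, nacp_index: int, opts: GenerationOptions) -> AtomicBasin:
    """Fan of descending paths from one NACP over icosahedral directions."""
    level = {12: 0, 42: 1, 162: 2, 642: 3}.get(opts.basin_directions)
    if level is None:
        raise TopologyError(
            f"basin_directions must be an icosphere vertex count (12/42/162/642), "
            f"got {opts.basin_directions}")
    dirs = icosphere_directions(level)
    paths = []
    for d in dirs:
        try:
            paths.append(trace_gradient_path(
                density, cps[nacp_index].position, d, "descending", cps,
                step=opts.trace_step, rho_floor=opts.rho_floor, cp_start=nacp_index))
        except TracingError as exc:
            log.warning("NACP %d basin trace failed: %s", nacp_index, exc)
    return AtomicBasin(nacp=nacp_index, paths=paths)


def build_envelope(density, cps, nacp_index: int,
                   isovalue: float = 0.001,
                   subdivision_level: int = 3,
                   rel_tol: float = 1e-8,
                   r_max: float = 50.0) -> Envelope:
    """Constant-density envelope around one NACP.

    For every direction of an icosahedral subdivision mesh the outermost
    radius with rho = isovalue is found by bracketing on a radial grid
    and bisection; the triangulation inherits the icosphere connectivity.
    """
    center = cps[nacp_index].position
    rho_c = float(density.rho(center[None])[0])
    if not isovalue < rho_c:
        raise TopologyError(
            f"isovalue {isovalue} not below density at the NACP ({rho_c:.3e})")
    mesh = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=1.0)
    dirs = np.asarray(mesh.vertices, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    n = len(dirs)
    # outermost bracketing interval on a coarse radial grid
    radii = np.linspace(0.05, r_max, 600)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    vals_prev = density.rho(center[None] + radii[0] * dirs)
    for k in range(1, len(radii)):
        vals = density.rho(center[None] + radii[k] * dirs)
        crossing = (vals_prev >= isovalue) & (vals < isovalue)
        lo[crossing] = radii[k - 1]
        hi[crossing] = radii[k]
        vals_prev = vals
    if np.any(np.isnan(lo)):
        raise TopologyError(
            f"envelope ray never crossed isovalue {isovalue} within {r_max} bohr")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        vals = density.rho(center[None] + mid[:, None] * dirs)
        above = vals >= isovalue
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
        if np.max(np.abs(vals / isovalue - 1.0)) < rel_tol:
            break
    r_iso = 0.5 * (lo + hi)
    verts = center[None] + r_iso[:, None] * dirs
    faces = np.asarray(mesh.faces, dtype=int)
    pairs = np.sort(np.vstack([faces[:, [0, 1]], faces[:, [1, 2]],
                               faces[:, [2, 0]]]), axis=1)
    edges = np.unique(pairs, axis=0)
    tri = Triangulation(vertices=verts, edges=edges, faces=faces)
    return Envelope(nacp=nacp_index, isovalue=isovalue, mesh=tri)


def build_interatomic_surface(density, cps, bcp_index: int,
                              opts: GenerationOptions | None = None,
                              n_samples: int = 16,
                              seed_eps: float = 1e-3) -> InteratomicSurface:
    """Interatomic surface of one bond CP.

    Descending traces are seeded on rings of radius ``seed_eps * 2**k``
    (k = 0..n_rings-1) in the BCP's lambda1-lambda2 eigenplane; the mesh
    joins the innermost-seeded path of consecutive angular directions at
    matched arc-length fractions into triangle strips around a central
    BCP vertex.
    """
    opts = opts or GenerationOptions()
    cp = cps[bcp_index]
    if not cp.is_bcp:
        raise TopologyError(f"CP {bcp_index} is not a bond CP")
    v1, v2 = _eigvec(cp, 0), _eigvec(cp, 1)
    n_ang, n_rad = opts.ias_angular, opts.ias_rings
    paths, per_angle = [], []
    for j in range(n_ang):
        th = 2.0 * math.pi * j / n_ang
        d = math.cos(th) * v1 + math.sin(th) * v2
        first = None
        for k in range(n_rad):
            try:
                p = trace_gradient_path(
                    density, cp.position, d, "descending", cps,
                    step=opts.trace_step, rho_floor=opts.rho_floor,
                    seed_offset=seed_eps * 2.0 ** k, cp_start=bcp_index)
            except TracingError as exc:
                log.warning("BCP %d IAS trace failed: %s", bcp_index, exc)
                continue
            paths.append(p)
            if first is None:
                first = p
        per_angle.append(first)

    # triangle strips over matched arc-length samples of the innermost paths
    rows = []
    for p in per_angle:
        if p is None:
            rows.append(None)
            continue
        pts = p.points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        fr = np.linspace(0.0, 1.0, n_samples + 1)[1:] * s[-1]
        rows.append(np.column_stack([np.interp(fr, s, pts[:, i]) for i in range(3)]))
    mesh = None
    if all(r is not None for r in rows):
        verts = [cp.position.copy()]
        for r in rows:
            verts.extend(r)
        verts = np.array(verts)
        faces = []
        for j in range(n_ang):
            a = 1 + j * n_samples
            b = 1 + ((j + 1) % n_ang) * n_samples
            faces.append([0, a, b])
            for k in range(n_samples - 1):
                faces.append([a + k, a + k + 1, b + k])
                faces.append([a + k + 1, b + k + 1, b + k])
        mesh = Triangulation(vertices=verts, faces=np.array(faces, dtype=int))
    return InteratomicSurface(bcp=bcp_index, paths=paths, mesh=mesh)


# ----------------------------------------------------------------------
# pipeline


def generate_topology(geometry: FixtureGeometry,
                      options: GenerationOptions | None = None) -> Topology:
    """Complete synthetic topology of a nuclear geometry."""
    opts = options or GenerationOptions()
    density = PromolecularDensity(geometry.nuclei)
    cps = find_critical_points(density)
    source = SourceInformation(
        qm_method="promolecular",
        basis_set="shell-resolved exponential terms",
        wavefunction_program="none",
        qct_program="qctviz")
    gvf = GradientVectorField()

    if opts.molecular_graph:
        ail_paths = build_ails(density, cps, opts)
        gvf.molecular_graph = assemble_molecular_graph(ail_paths, cps)

    if opts.rings or opts.cages:
        ring_surfaces = [build_ring_surface(density, cps, i, opts)
                         for i, cp in enumerate(cps) if cp.is_rcp]
        ccp_links = link_cages(density, cps, opts) if opts.cages else None
        rings, cages = assemble_rings_and_cages(
            gvf.molecular_graph, ring_surfaces, cps, ccp_links)
        if opts.rings:
            gvf.ring_surfaces = ring_surfaces
            gvf.rings = rings
        if opts.cages:
            gvf.cages = cages

    if opts.basins:
        gvf.basins = [build_basin(density, cps, i, opts)
                      for i, cp in enumerate(cps) if cp.is_nacp]

    if opts.interatomic_surfaces:
        ias_by_bcp = {i: build_interatomic_surface(density, cps, i, opts)
                      for i, cp in enumerate(cps) if cp.is_bcp}
        surfaces = []
        for i, cp in enumerate(cps):
            if not cp.is_nacp:
                continue
            member = [ias_by_bcp[a.bcp] for a in gvf.molecular_graph.ails
                      if i in a.nacp_pair() and a.bcp in ias_by_bcp]
            if member:
                surfaces.append(AtomicSurface(nacp=i, interatomic_surfaces=member))
        gvf.atomic_surfaces = surfaces

    if opts.envelopes:
        gvf.envelopes = [
            build_envelope(density, cps, i,
                           isovalue=opts.envelope_isovalue,
                           subdivision_level=opts.envelope_subdivision)
            for i, cp in enumerate(cps) if cp.is_nacp]

    return Topology(source=source, nuclei=list(geometry.nuclei),
                    critical_points=cps, gvf=gvf)
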