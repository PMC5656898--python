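"""Typed in-memory model of a scalar-field topology.

The model follows the object vocabulary of quantum chemical topology
(QTAIM): a :class:`Topology` owns nuclei, critical points (CPs) and a
gradient vector field built from gradient paths.  CPs are classified by
rank ``omega`` (number of non-zero Hessian eigenvalues) and signature
``sigma`` (sum of their signs): nuclear attractors (3,-3), bond CPs
(3,-1), ring CPs (3,+1) and cage CPs (3,+3); anything with rank < 3 is
degenerate.  Composite objects — atomic interaction lines, the molecular
graph, rings, cages, basins, interatomic surfaces, envelopes — are
assembled from gradient paths that connect pairs of CPs.

All coordinates are in bohr; density values in atomic units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

log = logging.getLogger(__name__)

#: Reserved sentinel CP index for gradient paths truncated "at infinity"
#: (density fell below the tracing floor before reaching a CP).
INFINITY: int = -1

#: Degeneracy tolerance on Hessian eigenvalues (au): |lambda| below this
#: counts as zero when computing rank and signature.
ZERO_TOL: float = 1e-8

#: Identity tolerance between a path endpoint and the CP it references (bohr).
SNAP_TOL: float = 1e-4

#: CPs closer than this are considered duplicates and merged (bohr).
MERGE_TOL: float = 1e-3

LABEL_NACP = "NACP"
LABEL_BCP = "BCP"
LABEL_RCP = "RCP"
LABEL_CCP = "CCP"
LABEL_DEGENERATE = "degenerate"

_SIGNATURE_LABELS = {-3: LABEL_NACP, -1: LABEL_BCP, +1: LABEL_RCP, +3: LABEL_CCP}


class TopologyError(ValueError):
    """Raised when a model invariant is violated."""


def as_position(p) -> np.ndarray:
    """Coerce to a finite float64 array of shape (3,)."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise TopologyError(f"position must have shape (3,), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise TopologyError(f"position has non-finite components: {a}")
    return a


def classify_critical_point(eigenvalues, zero_tol: float = ZERO_TOL):
    """Rank/signature classification of a CP from its Hessian eigenvalues.

    Parameters
    ----------
    eigenvalues : array-like of 3 floats, sorted ascending
        Eigenvalues of the Hessian of the scalar field at the CP.
    zero_tol : float
        Eigenvalues with ``|lambda| <= zero_tol`` count as zero.

    Returns
    -------
    (rank, signature, label)
        ``rank`` is the number of non-zero eigenvalues, ``signature`` the
        sum of their signs, and ``label`` one of ``NACP``/``BCP``/``RCP``/
        ``CCP`` for rank-3 points or ``degenerate`` otherwise.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.shape != (3,):
        raise TopologyError("expected exactly 3 eigenvalues")
    if not np.all(np.isfinite(ev)):
        raise TopologyError(f"non-finite eigenvalue in {ev}")
    if not (ev[0] <= ev[1] + zero_tol and ev[1] <= ev[2] + zero_tol):
        raise TopologyError(f"eigenvalues must be sorted ascending: {ev}")
    if zero_tol <= 0:
        raise TopologyError("zero_tol must be positive")
    nonzero = np.abs(ev) > zero_tol
    rank = int(np.count_nonzero(nonzero))
    signature = int(np.sum(np.sign(ev[nonzero])))
    if rank == 3:
        label = _SIGNATURE_LABELS[signature]
    else:
        label = LABEL_DEGENERATE
    return rank, signature, label


def poincare_hopf_residual(n_nacp: int, n_bcp: int, n_rcp: int, n_ccp: int) -> int:
    """n - b + r - c; equals 1 for the complete CP census of an isolated,
    connected system."""
    for v in (n_nacp, n_bcp, n_rcp, n_ccp):
        if v < 0:
            raise TopologyError("CP counts must be non-negative")
    return n_nacp - n_bcp + n_rcp - n_ccp


@dataclass
class Point:
    """A point in space carrying an open map of named scalar values
    (e.g. ``"rho"`` -> electron density in au)."""

    position: np.ndarray
    scalars: dict = field(default_factory=dict)

    def __post_init__(self):
        self.position = as_position(self.position)
        for k, v in self.scalars.items():
            if not isinstance(k, str) or not k:
                raise TopologyError("scalar map keys must be non-empty strings")
            if not math.isfinite(v):
                raise TopologyError(f"scalar {k!r} is non-finite")


@dataclass
class CriticalPoint(Point):
    """A Point where the gradient of the field vanishes, classified by
    rank and signature.

    ``eigenvalues``/``eigenvectors`` (of the Hessian at the CP) are
    optional: nuclear attractors of cusped densities carry none.
    """

    rank: int = 3
    signature: int = -3
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None

    def __post_init__(self):
        super().__post_init__()
        if self.rank not in (0, 1, 2, 3):
            raise TopologyError(f"rank must be in 0..3, got {self.rank}")
        if abs(self.signature) > self.rank:
            raise TopologyError(
                f"|signature| <= rank violated: ({self.rank},{self.signature})")
        if (self.signature - self.rank) % 2 != 0:
            raise TopologyError(
                f"signature == rank (mod 2) violated: ({self.rank},{self.signature})")
        if self.eigenvalues is not None:
            ev = np.asarray(self.eigenvalues, dtype=float)
            rank, signature, _ = classify_critical_point(ev)
            if (rank, signature) != (self.rank, self.signature):
                raise TopologyError(
                    f"stored rank/signature ({self.rank},{self.signature}) disagree "
                    f"with eigenvalues {ev} -> ({rank},{signature})")
            self.eigenvalues = ev
        if self.eigenvectors is not None:
            vecs = np.asarray(self.eigenvectors, dtype=float)
            if vecs.shape != (3, 3):
                raise TopologyError("eigenvectors must be a 3x3 array (rows)")
            self.eigenvectors = vecs

    @property
    def label(self) -> str:
        if self.rank == 3:
            return _SIGNATURE_LABELS[self.signature]
        return LABEL_DEGENERATE

    @property
    def is_nacp(self) -> bool:
        return self.rank == 3 and self.signature == -3

    @property
    def is_bcp(self) -> bool:
        return self.rank == 3 and self.signature == -1

    @property
    def is_rcp(self) -> bool:
        return self.rank == 3 and self.signature == +1

    @property
    def is_ccp(self) -> bool:
        return self.rank == 3 and self.signature == +3


@dataclass
class Nucleus:
    element: str
    position: np.ndarray
    index: int

    def __post_init__(self):
        from .elements import is_known_element
        self.position = as_position(self.position)
        if self.index < 0:
            raise TopologyError("nucleus index must be >= 0")
        if not is_known_element(self.element):
            raise TopologyError(f"unrecognized element symbol {self.element!r}")


@dataclass
class GradientPath:
    """Ordered polyline along the gradient field connecting two CPs.

    ``points`` is an (N, 3) array (N >= 2); ``scalars`` maps a function
    name to per-point values of length N.  ``cp_end`` may be the
    :data:`INFINITY` sentinel for paths truncated at the density floor.
    """

    points: np.ndarray
    cp_start: int
    cp_end: int
    scalars: dict = field(default_factory=dict)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise TopologyError("path needs an (N>=2, 3) point array")
        if not np.all(np.isfinite(pts)):
            raise TopologyError("path contains non-finite points")
        if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise TopologyError("consecutive path points must be distinct")
        self.points = pts
        for k, v in self.scalars.items():
            arr = np.asarray(v, dtype=float)
            if arr.shape != (pts.shape[0],):
                raise TopologyError(f"scalar array {k!r} length mismatch")
            self.scalars[k] = arr

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def point(self, i: int) -> Point:
        return Point(self.points[i], {k: float(v[i]) for k, v in self.scalars.items()})

    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class AtomicInteractionLine:
    """Two gradient paths sharing a bond CP and ending at two distinct
    nuclear attractors; a 'bond path' at equilibrium geometry."""

    paths: list
    bcp: int

    def __post_init__(self):
        if len(self.paths) != 2:
            raise TopologyError("an AIL consists of exactly 2 gradient paths")
        for p in self.paths:
            if self.bcp not in (p.cp_start, p.cp_end):
                raise TopologyError("both AIL paths must reference the shared BCP")

    def nacp_pair(self) -> tuple[int, int]:
        """The two far-end CP indices, sorted."""
        ends = []
        for p in self.paths:
            ends.append(p.cp_end if p.cp_start == self.bcp else p.cp_start)
        return tuple(sorted(ends))


@dataclass
class MolecularGraph:
    """The set of all AILs of a system: its first-principles connectivity."""

    ails: list = field(default_factory=list)

    def __post_init__(self):
        bcps = [a.bcp for a in self.ails]
        if len(bcps) != len(set(bcps)):
            raise TopologyError("no two AILs may share the same BCP")

    def as_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for i, ail in enumerate(self.ails):
            a, b = ail.nacp_pair()
            g.add_edge(a, b, ail=i, bcp=ail.bcp)
        return g


@dataclass
class Ring:
    """>= 3 AILs forming a closed NACP cycle around a ring CP."""

    ails: list  # indices into MolecularGraph.ails
    rcp: int

    def __post_init__(self):
        if len(self.ails) < 3:
            raise TopologyError("a ring needs at least 3 AILs")


@dataclass
class Cage:
    """>= 2 rings enclosing a cage CP."""

    rings: list  # indices into GradientVectorField.rings
    ccp: int

    def __post_init__(self):
        if len(self.rings) < 2:
            raise TopologyError("a cage needs at least 2 rings")


@dataclass
class AtomicBasin:
    """Bundle of gradient paths originating at one NACP — the QCT atom."""

    nacp: int
    paths: list = field(default_factory=list)

    def __post_init__(self):
        for p in self.paths:
            if p.cp_start != self.nacp:
                raise TopologyError("every basin path must start at the basin NACP")


@dataclass
class Triangulation:
    """Indexed mesh: (V,3) vertices, (E,2) edges, (F,3) faces."""

    vertices: np.ndarray
    edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    faces: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise TopologyError("vertices must be (V, 3)")
        e = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        f = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        n = v.shape[0]
        if e.size and (e.min() < 0 or e.max() >= n):
            raise TopologyError("edge index out of range")
        if f.size:
            if f.min() < 0 or f.max() >= n:
                raise TopologyError("face index out of range")
            degenerate = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            if np.any(degenerate):
                raise TopologyError("degenerate face (repeated vertex)")
        self.vertices, self.edges, self.faces = v, e, f

    def euler_characteristic(self) -> int:
        """V - E + F with E derived from the face set (2 for a closed
        sphere-like surface)."""
        if not self.faces.size:
            return self.vertices.shape[0] - self.edges.shape[0]
        pairs = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                           self.faces[:, [2, 0]]])
        pairs = np.sort(pairs, axis=1)
        n_edges = np.unique(pairs, axis=0).shape[0]
        return self.vertices.shape[0] - n_edges + self.faces.shape[0]


@dataclass
class InteratomicSurface:
    """Separatrix surface: gradient paths descending from a shared BCP,
    optionally triangulated."""

    bcp: int
    paths: list = field(default_factory=list)
    mesh: Triangulation | None = None

    def __post_init__(self):
        for p in self.paths:
            if p.cp_start != self.bcp:
                raise TopologyError("every IAS path must start at the surface BCP")


@dataclass
class AtomicSurface:
    """Union of the interatomic surfaces bounding one atom."""

    nacp: int
    interatomic_surfaces: list = field(default_factory=list)


@dataclass
class RingSurface:
    """Bundle of ring paths (gradient paths rooted at a ring CP)."""

    rcp: int
    paths: list = field(default_factory=list)

    def __post_init__(self):
        for p in self.paths:
            if p.cp_start != self.rcp:
                raise TopologyError("every ring-surface path must start at the RCP")


@dataclass
class Envelope:
    """Constant-density isosurface around one atom (conventionally
    rho = 0.001 au), as a triangulated mesh."""

    nacp: int
    isovalue: float
    mesh: Triangulation
    points: list = field(default_factory=list)

    def __post_init__(self):
        if not self.isovalue > 0:
            raise TopologyError("envelope isovalue must be positive")


@dataclass
class SourceInformation:
    qm_method: str = ""
    basis_set: str = ""
    wavefunction_program: str = ""
    qct_program: str = ""


@dataclass
class GradientVectorField:
    molecular_graph: MolecularGraph = field(default_factory=MolecularGraph)
    rings: list = field(default_factory=list)
    cages: list = field(default_factory=list)
    atomic_surfaces: list = field(default_factory=list)
    ring_surfaces: list = field(default_factory=list)
    basins: list = field(default_factory=list)
    envelopes: list = field(default_factory=list)


@dataclass
class Topology:
    source: SourceInformation = field(default_factory=SourceInformation)
    nuclei: list = field(default_factory=list)
    critical_points: list = field(default_factory=list)
    gvf: GradientVectorField = field(default_factory=GradientVectorField)

    # -- census ---------------------------------------------------------

    def census(self) -> dict:
        counts = {LABEL_NACP: 0, LABEL_BCP: 0, LABEL_RCP: 0, LABEL_CCP: 0,
                  LABEL_DEGENERATE: 0}
        for cp in self.critical_points:
            counts[cp.label] += 1
        return counts

    def poincare_hopf_residual(self) -> int:
        c = self.census()
        return poincare_hopf_residual(c[LABEL_NACP], c[LABEL_BCP],
                                      c[LABEL_RCP], c[LABEL_CCP])

    def cp_indices(self, label: str) -> list:
        return [i for i, cp in enumerate(self.critical_points) if cp.label == label]

    # -- validation -----------------------------------------------------

    def _check_cp_ref(self, idx, what, problems, allow_infinity=False):
        if allow_infinity and idx == INFINITY:
            return
        if not (0 <= idx < len(self.critical_points)):
            problems.append(f"{what}: CP index {idx} does not resolve")

    def validate(self, snap_tol: float = SNAP_TOL) -> list:
        """Model-level consistency check; returns a list of problem strings
        (empty when the topology is sound)."""
        problems: list = []
        ncp = len(self.critical_points)
        nuc_pos = np.array([n.position for n in self.nuclei]).reshape(-1, 3)
        for i, cp in enumerate(self.critical_points):
            if cp.is_nacp and len(self.nuclei):
                d = np.linalg.norm(nuc_pos - cp.position, axis=1)
                if np.count_nonzero(d <= snap_tol) != 1:
                    problems.append(
                        f"NACP {i} does not lie within {snap_tol} bohr of exactly one nucleus")

        def check_path(p, what):
            self._check_cp_ref(p.cp_start, f"{what} cp_start", problems)
            self._check_cp_ref(p.cp_end, f"{what} cp_end", problems, allow_infinity=True)
            for which, idx, pt in (("start", p.cp_start, p.points[0]),
                                   ("end", p.cp_end, p.points[-1])):
                if idx == INFINITY or not (0 <= idx < ncp):
                    continue
                d = np.linalg.norm(self.critical_points[idx].position - pt)
                if d > snap_tol:
                    problems.append(
                        f"{what}: {which} point is {d:.2e} bohr from CP {idx} (> {snap_tol})")

        g = self.gvf
        for ia, ail in enumerate(g.molecular_graph.ails):
            self._check_cp_ref(ail.bcp, f"AIL {ia} bcp", problems)
            a, b = ail.nacp_pair()
            if a == b:
                problems.append(f"AIL {ia}: far endpoints are not distinct")
            for j, (idx, cp_ok) in enumerate(((a, True), (b, True))):
                if 0 <= idx < ncp and not self.critical_points[idx].is_nacp:
                    problems.append(f"AIL {ia}: far endpoint CP {idx} is not an NACP")
            for p in ail.paths:
                check_path(p, f"AIL {ia} path")
        for ir, ring in enumerate(g.rings):
            self._check_cp_ref(ring.rcp, f"Ring {ir} rcp", problems)
            if 0 <= ring.rcp < ncp and not self.critical_points[ring.rcp].is_rcp:
                problems.append(f"Ring {ir}: CP {ring.rcp} is not an RCP")
            for ai in ring.ails:
                if not (0 <= ai < len(g.molecular_graph.ails)):
                    problems.append(f"Ring {ir}: AIL index {ai} does not resolve")
        for ic, cage in enumerate(g.cages):
            self._check_cp_ref(cage.ccp, f"Cage {ic} ccp", problems)
            if 0 <= cage.ccp < ncp and not self.critical_points[cage.ccp].is_ccp:
                problems.append(f"Cage {ic}: CP {cage.ccp} is not a CCP")
        for collection, name, root in (
                (g.basins, "Basin", "nacp"),
                (g.ring_surfaces, "RingSurface", "rcp")):
            for k, obj in enumerate(collection):
                self._check_cp_ref(getattr(obj, root), f"{name} {k} {root}", problems)
                for p in obj.paths:
                    check_path(p, f"{name} {k} path")
        for k, surf in enumerate(g.atomic_surfaces):
            self._check_cp_ref(surf.nacp, f"AtomicSurface {k} nacp", problems)
            for ias in surf.interatomic_surfaces:
                self._check_cp_ref(ias.bcp, f"AtomicSurface {k} IAS bcp", problems)
        for k, env in enumerate(g.envelopes):
            self._check_cp_ref(env.nacp, f"Envelope {k} nacp", problems)
        return problems


# -- assembly ----------------------------------------------------------


def assemble_molecular_graph(paths, cps, snap_tol: float = SNAP_TOL) -> MolecularGraph:
    """Pair NACP-terminated gradient paths sharing one BCP into AILs.

    Paths that do not run BCP -> NACP are ignored.  A BCP with a number of
    NACP-terminated paths other than two is skipped with a warning.
    """
    by_bcp: dict = {}
    for p in paths:
        ends = {p.cp_start, p.cp_end}
        bcps = [i for i in ends
                if 0 <= i < len(cps) and cps[i].is_bcp]
        nacps = [i for i in ends
                 if 0 <= i < len(cps) and cps[i].is_nacp]
        if len(bcps) == 1 and len(nacps) == 1:
            by_bcp.setdefault(bcps[0], []).append(p)
    ails = []
    for bcp in sorted(by_bcp):
        group = by_bcp[bcp]
        if len(group) != 2:
            log.warning("BCP %d has %d NACP-terminated paths (expected 2); skipped",
                        bcp, len(group))
            continue
        ail = AtomicInteractionLine(paths=group, bcp=bcp)
        a, b = ail.nacp_pair()
        if a == b:
            log.warning("BCP %d: both paths reach the same NACP %d; skipped", bcp, a)
            continue
        ails.append(ail)
    return MolecularGraph(ails=ails)


def _is_single_cycle(graph: nx.MultiGraph) -> bool:
    if graph.number_of_nodes() < 3:
        return False
    return (nx.is_connected(graph)
            and graph.number_of_edges() == graph.number_of_nodes()
            and all(d == 2 for _, d in graph.degree()))


def assemble_rings_and_cages(graph: MolecularGraph, ring_surfaces, cps,
                             ccp_links: dict | None = None):
    """Build Ring and Cage objects.

    For each ring surface, the ring is the set of AILs whose BCPs are
    reached by its ring paths, accepted only if those AILs close into a
    single NACP cycle.  ``ccp_links`` maps a CCP index to the set of RCP
    indices whose descending paths reach it (computed by the tracing
    layer); each CCP's cage collects the rings of those RCPs.
    """
    bcp_to_ail = {ail.bcp: i for i, ail in enumerate(graph.ails)}
    rings = []
    for rs in ring_surfaces:
        bcps = sorted({p.cp_end for p in rs.paths
                       if 0 <= p.cp_end < len(cps) and cps[p.cp_end].is_bcp})
        if len(bcps) < 3:
            log.warning("RCP %d: ring paths reach only %d distinct BCPs; ring omitted",
                        rs.rcp, len(bcps))
            continue
        ail_idx = [bcp_to_ail[b] for b in bcps if b in bcp_to_ail]
        sub = nx.MultiGraph()
        for ai in ail_idx:
            a, b = graph.ails[ai].nacp_pair()
            sub.add_edge(a, b)
        if not _is_single_cycle(sub):
            log.warning("RCP %d: reached AILs do not close into a single cycle; "
                        "ring omitted", rs.rcp)
            continue
        rings.append(Ring(ails=sorted(ail_idx), rcp=rs.rcp))

    cages = []
    if ccp_links:
        ring_by_rcp = {r.rcp: i for i, r in enumerate(rings)}
        for ccp in sorted(ccp_links):
            members = sorted(ring_by_rcp[r] for r in ccp_links[ccp] if r in ring_by_rcp)
            if len(members) < 2:
                log.warning("CCP %d: fewer than 2 member rings; cage omitted", ccp)
                continue
            cages.append(Cage(rings=members, ccp=ccp))
    return rings, cages


# -- comparison helper (round-trip tests, idempotence checks) ----------


def topologies_allclose(a: Topology, b: Topology, atol: float = 1e-9) -> bool:
    """Structural equality of two topologies within a coordinate tolerance."""

    def pos_close(x, y):
        return np.allclose(x, y, atol=atol, rtol=0.0)

    def scalars_close(x, y):
        return set(x) == set(y) and all(np.allclose(x[k], y[k], atol=atol) for k in x)

    def paths_close(p, q):
        return (p.cp_start == q.cp_start and p.cp_end == q.cp_end
                and p.points.shape == q.points.shape
                and pos_close(p.points, q.points) and scalars_close(p.scalars, q.scalars))

    def pathlists_close(ps, qs):
        return len(ps) == len(qs) and all(paths_close(p, q) for p, q in zip(ps, qs))

    def mesh_close(m, n):
        if (m is None) != (n is None):
            return False
        if m is None:
            return True
        return (m.vertices.shape == n.vertices.shape and pos_close(m.vertices, n.vertices)
                and np.array_equal(m.edges, n.edges) and np.array_equal(m.faces, n.faces))

    if len(a.nuclei) != len(b.nuclei) or len(a.critical_points) != len(b.critical_points):
        return False
    if vars(a.source) != vars(b.source):
        return False
    for na, nb in zip(a.nuclei, b.nuclei):
        if na.element != nb.element or na.index != nb.index or not pos_close(na.position, nb.position):
            return False
    for ca, cb in zip(a.critical_points, b.critical_points):
        if (ca.rank, ca.signature) != (cb.rank, cb.signature):
            return False
        if not pos_close(ca.position, cb.position) or not scalars_close(ca.scalars, cb.scalars):
            return False
        if (ca.eigenvalues is None) != (cb.eigenvalues is None):
            return False
        if ca.eigenvalues is not None and not np.allclose(ca.eigenvalues, cb.eigenvalues, atol=atol):
            return False
    ga, gb = a.gvf, b.gvf
    if len(ga.molecular_graph.ails) != len(gb.molecular_graph.ails):
        return False
    for xa, xb in zip(ga.molecular_graph.ails, gb.molecular_graph.ails):
        if xa.bcp != xb.bcp or not pathlists_close(xa.paths, xb.paths):
            return False
    if [(r.rcp, r.ails) for r in ga.rings] != [(r.rcp, r.ails) for r in gb.rings]:
        return False
    if [(c.ccp, c.rings) for c in ga.cages] != [(c.ccp, c.rings) for c in gb.cages]:
        return False
    for la, lb in ((ga.basins, gb.basins), (ga.ring_surfaces, gb.ring_surfaces)):
        if len(la) != len(lb):
            return False
        for oa, ob in zip(la, lb):
            if not pathlists_close(oa.paths, ob.paths):
                return False
    if len(ga.atomic_surfaces) != len(gb.atomic_surfaces):
        return False
    for sa, sb in zip(ga.atomic_surfaces, gb.atomic_surfaces):
        if sa.nacp != sb.nacp or len(sa.interatomic_surfaces) != len(sb.interatomic_surfaces):
            return False
        for ia, ib in zip(sa.interatomic_surfaces, sb.interatomic_surfaces):
            if ia.bcp != ib.bcp or not pathlists_close(ia.paths, ib.paths):
                return False
            if not mesh_close(ia.mesh, ib.mesh):
                return False
    if len(ga.envelopes) != len(gb.envelopes):
        return False
    for ea, eb in zip(ga.envelopes, gb.envelopes):
        if ea.nacp != eb.nacp or not np.isclose(ea.isovalue, eb.isovalue, atol=atol):
            return False
        if not mesh_close(ea.mesh, eb.mesh):
            return False
    return True
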