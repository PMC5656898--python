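"""Read, write and validate the ``.top`` XML topology format.

The format is defined by the DTD shipped at ``qctviz/data/Topology.dtd``;
element names mirror the topology class vocabulary (Topology, Nucleus,
CriticalPoint, GradientVectorField, MolecularGraph, AtomicInteractionLine,
GradientPath, Ring, Cage, AtomicSurface, InteratomicSurface, RingSurface,
AtomicBasin, Envelope, Triangulation, Point, PositionVector).  Coordinates
are stored in bohr; all indices are 0-based; numeric attributes carry 12
significant digits.  Files are UTF-8 only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from lxml import etree

from .model import (
    INFINITY,
    AtomicBasin,
    AtomicInteractionLine,
    AtomicSurface,
    Cage,
    CriticalPoint,
    Envelope,
    GradientPath,
    GradientVectorField,
    InteratomicSurface,
    MolecularGraph,
    Nucleus,
    Ring,
    RingSurface,
    SourceInformation,
    Topology,
    TopologyError,
    Triangulation,
)

ERROR = "error"
WARNING = "warning"


class SerializationError(ValueError):
    """Raised when a topology cannot be written (unresolvable references)."""


class ValidationError(ValueError):
    """Raised by the reader on files that fail DTD or model validation."""


@dataclass
class ValidationReport:
    messages: list = field(default_factory=list)  # (severity, xml_path, text)

    @property
    def valid(self) -> bool:
        return not any(sev == ERROR for sev, _, _ in self.messages)

    def add(self, severity: str, path: str, text: str) -> None:
        self.messages.append((severity, path, text))

    def errors(self) -> list:
        return [m for m in self.messages if m[0] == ERROR]


def _dtd() -> etree.DTD:
    with resources.files("qctviz.data").joinpath("Topology.dtd").open("rb") as f:
        return etree.DTD(f)


def _fmt(value: float) -> str:
    return f"{float(value):.12g}"


# ----------------------------------------------------------------------
# writing


def _pos_el(parent, tag, p):
    etree.SubElement(parent, tag, x=_fmt(p[0]), y=_fmt(p[1]), z=_fmt(p[2]))


def _point_el(parent, position, scalars):
    el = etree.SubElement(parent, "Point")
    _pos_el(el, "PositionVector", position)
    for name in sorted(scalars):
        etree.SubElement(el, "Scalar", name=name, value=_fmt(scalars[name]))


def _path_el(parent, path: GradientPath):
    attrs = {"cp_start": str(path.cp_start)}
    if path.cp_end == INFINITY:
        attrs["terminus"] = "infinity"
    else:
        attrs["cp_end"] = str(path.cp_end)
    el = etree.SubElement(parent, "GradientPath", **attrs)
    for i in range(path.n_points):
        _point_el(el, path.points[i],
                  {k: v[i] for k, v in path.scalars.items()})


def _tri_el(parent, tri: Triangulation):
    el = etree.SubElement(parent, "Triangulation")
    for v in tri.vertices:
        vert = etree.SubElement(el, "Vertex")
        _pos_el(vert, "PositionVector", v)
    for a, b in tri.edges:
        etree.SubElement(el, "Edge", a=str(int(a)), b=str(int(b)))
    for a, b, c in tri.faces:
        etree.SubElement(el, "Face", a=str(int(a)), b=str(int(b)), c=str(int(c)))


def _check_writable(topology: Topology) -> None:
    unresolved = [p for p in topology.validate() if "does not resolve" in p]
    if unresolved:
        raise SerializationError(
            "cannot serialize topology with unresolvable CP references: "
            + "; ".join(unresolved))


def write_topology(topology: Topology, destination) -> None:
    """Serialize to ``.top`` XML (UTF-8, DTD-conforming).

    ``destination`` may be a path or a binary file-like object.
    """
    _check_writable(topology)
    root = etree.Element("Topology", unit="bohr")
    src = topology.source
    etree.SubElement(root, "SourceInformation",
                     qm_method=src.qm_method, basis_set=src.basis_set,
                     wavefunction_program=src.wavefunction_program,
                     qct_program=src.qct_program)
    for nuc in topology.nuclei:
        el = etree.SubElement(root, "Nucleus", index=str(nuc.index),
                              element=nuc.element)
        _pos_el(el, "PositionVector", nuc.position)
    for i, cp in enumerate(topology.critical_points):
        el = etree.SubElement(root, "CriticalPoint", index=str(i),
                              rank=str(cp.rank), signature=str(cp.signature))
        _point_el(el, cp.position, cp.scalars)
        if cp.eigenvalues is not None:
            etree.SubElement(el, "Eigenvalues", l1=_fmt(cp.eigenvalues[0]),
                             l2=_fmt(cp.eigenvalues[1]), l3=_fmt(cp.eigenvalues[2]))
        if cp.eigenvectors is not None:
            ev = etree.SubElement(el, "Eigenvectors")
            for row in cp.eigenvectors:
                _pos_el(ev, "PositionVector", row)

    g = topology.gvf
    gel = etree.SubElement(root, "GradientVectorField")
    mg = etree.SubElement(gel, "MolecularGraph")
    for ail in g.molecular_graph.ails:
        ael = etree.SubElement(mg, "AtomicInteractionLine", bcp=str(ail.bcp))
        for p in ail.paths:
            _path_el(ael, p)
    for ring in g.rings:
        rel = etree.SubElement(gel, "Ring", rcp=str(ring.rcp))
        for ai in ring.ails:
            etree.SubElement(rel, "AilRef", index=str(ai))
    for cage in g.cages:
        cel = etree.SubElement(gel, "Cage", ccp=str(cage.ccp))
        for ri in cage.rings:
            etree.SubElement(cel, "RingRef", index=str(ri))
    for surf in g.atomic_surfaces:
        sel = etree.SubElement(gel, "AtomicSurface", nacp=str(surf.nacp))
        for ias in surf.interatomic_surfaces:
            iel = etree.SubElement(sel, "InteratomicSurface", bcp=str(ias.bcp))
            for p in ias.paths:
                _path_el(iel, p)
            if ias.mesh is not None:
                _tri_el(iel, ias.mesh)
    for rs in g.ring_surfaces:
        rel = etree.SubElement(gel, "RingSurface", rcp=str(rs.rcp))
        for p in rs.paths:
            _path_el(rel, p)
    for basin in g.basins:
        bel = etree.SubElement(gel, "AtomicBasin", nacp=str(basin.nacp))
        for p in basin.paths:
            _path_el(bel, p)
    for env in g.envelopes:
        eel = etree.SubElement(gel, "Envelope", nacp=str(env.nacp),
                               isovalue=_fmt(env.isovalue))
        for pt in env.points:
            _point_el(eel, pt.position, pt.scalars)
        _tri_el(eel, env.mesh)

    tree = etree.ElementTree(root)
    data = etree.tostring(tree, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True,
                          doctype='<!DOCTYPE Topology SYSTEM "Topology.dtd">')
    if hasattr(destination, "write"):
        destination.write(data)
    else:
        with open(destination, "wb") as f:
            f.write(data)


# ----------------------------------------------------------------------
# reading


def _parse_pos(el) -> np.ndarray:
    return np.array([float(el.get("x")), float(el.get("y")), float(el.get("z"))])


def _parse_point(el):
    pos = _parse_pos(el.find("PositionVector"))
    scalars = {s.get("name"): float(s.get("value")) for s in el.findall("Scalar")}
    return pos, scalars


def _parse_path(el) -> GradientPath:
    pts, per_point = [], []
    for pel in el.findall("Point"):
        pos, scal = _parse_point(pel)
        pts.append(pos)
        per_point.append(scal)
    names = set().union(*per_point) if per_point else set()
    scalars = {}
    for name in names:
        scalars[name] = np.array([d.get(name, np.nan) for d in per_point])
    if el.get("terminus") == "infinity":
        cp_end = INFINITY
    else:
        cp_end = int(el.get("cp_end"))
    return GradientPath(points=np.array(pts), cp_start=int(el.get("cp_start")),
                        cp_end=cp_end, scalars=scalars)


def _parse_tri(el) -> Triangulation:
    verts = [_parse_pos(v.find("PositionVector")) for v in el.findall("Vertex")]
    edges = [[int(e.get("a")), int(e.get("b"))] for e in el.findall("Edge")]
    faces = [[int(f.get("a")), int(f.get("b")), int(f.get("c"))]
             for f in el.findall("Face")]
    return Triangulation(vertices=np.array(verts).reshape(-1, 3),
                         edges=np.array(edges, dtype=int).reshape(-1, 2),
                         faces=np.array(faces, dtype=int).reshape(-1, 3))


def _parse_tree(root, simple: bool) -> Topology:
    unit = root.get("unit")
    if unit != "bohr":
        raise ValidationError(
            f"unsupported unit {unit!r}: this reader accepts bohr only")
    sel = root.find("SourceInformation")
    source = SourceInformation(
        qm_method=sel.get("qm_method") or "",
        basis_set=sel.get("basis_set") or "",
        wavefunction_program=sel.get("wavefunction_program") or "",
        qct_program=sel.get("qct_program") or "")
    nuclei = []
    for el in root.findall("Nucleus"):
        nuclei.append(Nucleus(element=el.get("element"),
                              position=_parse_pos(el.find("PositionVector")),
                              index=int(el.get("index"))))
    cps = []
    for el in root.findall("CriticalPoint"):
        pos, scalars = _parse_point(el.find("Point"))
        ev_el = el.find("Eigenvalues")
        evals = None
        if ev_el is not None:
            evals = np.array([float(ev_el.get("l1")), float(ev_el.get("l2")),
                              float(ev_el.get("l3"))])
        vec_el = el.find("Eigenvectors")
        evecs = None
        if vec_el is not None:
            evecs = np.array([_parse_pos(p) for p in vec_el.findall("PositionVector")])
        cps.append(CriticalPoint(position=pos, scalars=scalars,
                                 rank=int(el.get("rank")),
                                 signature=int(el.get("signature")),
                                 eigenvalues=evals, eigenvectors=evecs))
    gvf = GradientVectorField()
    gel = root.find("GradientVectorField")
    if gel is not None:
        mg = gel.find("MolecularGraph")
        if mg is not None:
            ails = []
            for ael in mg.findall("AtomicInteractionLine"):
                paths = [_parse_path(p) for p in ael.findall("GradientPath")]
                ails.append(AtomicInteractionLine(paths=paths, bcp=int(ael.get("bcp"))))
            gvf.molecular_graph = MolecularGraph(ails=ails)
        if not simple:
            for rel in gel.findall("Ring"):
                gvf.rings.append(Ring(
                    ails=[int(a.get("index")) for a in rel.findall("AilRef")],
                    rcp=int(rel.get("rcp"))))
            for cel in gel.findall("Cage"):
                gvf.cages.append(Cage(
                    rings=[int(r.get("index")) for r in cel.findall("RingRef")],
                    ccp=int(cel.get("ccp"))))
            for sel_ in gel.findall("AtomicSurface"):
                surfaces = []
                for iel in sel_.findall("InteratomicSurface"):
                    tri_el = iel.find("Triangulation")
                    surfaces.append(InteratomicSurface(
                        bcp=int(iel.get("bcp")),
                        paths=[_parse_path(p) for p in iel.findall("GradientPath")],
                        mesh=None if tri_el is None else _parse_tri(tri_el)))
                gvf.atomic_surfaces.append(
                    AtomicSurface(nacp=int(sel_.get("nacp")),
                                  interatomic_surfaces=surfaces))
            for rel in gel.findall("RingSurface"):
                gvf.ring_surfaces.append(RingSurface(
                    rcp=int(rel.get("rcp")),
                    paths=[_parse_path(p) for p in rel.findall("GradientPath")]))
            for bel in gel.findall("AtomicBasin"):
                gvf.basins.append(AtomicBasin(
                    nacp=int(bel.get("nacp")),
                    paths=[_parse_path(p) for p in bel.findall("GradientPath")]))
            for eel in gel.findall("Envelope"):
                gvf.envelopes.append(Envelope(
                    nacp=int(eel.get("nacp")),
                    isovalue=float(eel.get("isovalue")),
                    mesh=_parse_tri(eel.find("Triangulation"))))
    return Topology(source=source, nuclei=nuclei, critical_points=cps, gvf=gvf)


def _load_tree(source):
    parser = etree.XMLParser(remove_blank_text=False)
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            data = data.encode("utf-8")
        return etree.parse(io.BytesIO(data), parser)
    return etree.parse(str(source), parser)


def read_topology(source, simple: bool = False) -> Topology:
    """Parse and validate a ``.top`` file into the in-memory model.

    With ``simple=True`` only critical points and the molecular graph are
    populated (rings, cages, basins, surfaces and envelopes are dropped),
    mirroring a 'simple topology' import.
    """
    try:
        tree = _load_tree(source)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ValidationError(f"cannot parse XML: {exc}") from exc
    dtd = _dtd()
    if not dtd.validate(tree):
        msgs = "; ".join(f"{e.line}: {e.message}" for e in dtd.error_log
                         .filter_from_errors())
        raise ValidationError(f"DTD validation failed: {msgs}")
    try:
        return _parse_tree(tree.getroot(), simple=simple)
    except TopologyError as exc:
        raise ValidationError(f"model validation failed: {exc}") from exc


def validate_top(source) -> ValidationReport:
    """Validate a ``.top`` file; all problems land in the report."""
    report = ValidationReport()
    try:
        tree = _load_tree(source)
    except etree.XMLSyntaxError as exc:
        report.add(ERROR, "/", f"XML parse error: {exc}")
        return report
    except OSError as exc:
        report.add(ERROR, "/", f"cannot read source: {exc}")
        return report
    dtd = _dtd()
    if not dtd.validate(tree):
        for e in dtd.error_log.filter_from_errors():
            report.add(ERROR, f"line {e.line}", e.message)
        return report
    root = tree.getroot()
    try:
        # model constructors enforce CP rank/signature legality; their
        # messages (e.g. "signature == rank (mod 2) violated") surface here
        topology = _parse_tree(root, simple=False)
    except (TopologyError, ValidationError, ValueError) as exc:
        report.add(ERROR, root.tag, str(exc))
        return report
    for problem in topology.validate():
        report.add(ERROR, "Topology", problem)
    return report
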