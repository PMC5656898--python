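"""Idealized nuclear geometries for synthetic topology generation.

Each builder returns a symmetric, textbook geometry constructed from
internal coordinates (bond lengths in angstrom, converted to bohr).
An XYZ reader accepts arbitrary external geometries in the standard
two-line-header format.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, fsolve

from .model import Nucleus, TopologyError
from .units import angstrom_to_bohr

TETRAHEDRAL_COS = -1.0 / 3.0  # cos(109.471 deg)


@dataclass
class FixtureGeometry:
    name: str
    nuclei: list = field(default_factory=list)

    def __post_init__(self):
        pos = np.array([n.position for n in self.nuclei])
        if len(pos) >= 2:
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            iu = np.triu_indices(len(pos), k=1)
            if d[iu].min() <= 0.5:
                raise TopologyError(
                    f"fixture {self.name!r}: interatomic distance <= 0.5 bohr")

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nuclei])


def _nuclei(symbols, coords_angstrom):
    coords = angstrom_to_bohr(np.asarray(coords_angstrom, dtype=float))
    return [Nucleus(element=s, position=c, index=i)
            for i, (s, c) in enumerate(zip(symbols, coords))]


def _methyl_h_directions(u_anti: np.ndarray) -> list:
    """Three unit vectors at tetrahedral angle from -u_anti (the bond the
    carbon already has), spaced 120 deg about that bond axis."""
    axis = u_anti / np.linalg.norm(u_anti)
    # any perpendicular
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, axis)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    perp = seed - np.dot(seed, axis) * axis
    perp /= np.linalg.norm(perp)
    out = []
    s, c = math.sin(math.acos(TETRAHEDRAL_COS)), TETRAHEDRAL_COS
    for k in range(3):
        ang = 2.0 * math.pi * k / 3.0
        p = math.cos(ang) * perp + math.sin(ang) * np.cross(axis, perp)
        out.append(c * axis + s * p)
    return out


def _bridging_h_directions(u1: np.ndarray, u2: np.ndarray) -> list:
    """Two unit vectors completing a tetrahedral center whose first two
    bonds point along u1 and u2."""
    b = u1 + u2
    b /= np.linalg.norm(b)
    p = np.cross(u1, u2)
    p /= np.linalg.norm(p)
    alpha = TETRAHEDRAL_COS / np.dot(b, u1)
    beta = math.sqrt(max(0.0, 1.0 - alpha * alpha))
    return [alpha * b + beta * p, alpha * b - beta * p]


def _benzene():
    # D6h in the xy-plane: hexagon side = ring radius = C-C distance.
    rcc, rch = 1.3915, 1.0800
    symbols, coords = [], []
    for k in range(6):
        a = math.pi * k / 3.0
        symbols.append("C")
        coords.append([rcc * math.cos(a), rcc * math.sin(a), 0.0])
    for k in range(6):
        a = math.pi * k / 3.0
        symbols.append("H")
        coords.append([(rcc + rch) * math.cos(a), (rcc + rch) * math.sin(a), 0.0])
    return symbols, coords


def _h2():
    return ["H", "H"], [[0.0, 0.0, -0.37], [0.0, 0.0, 0.37]]


def _hcn():
    # linear C-inf-v: H-C 1.066, C-N 1.153
    return ["H", "C", "N"], [[0.0, 0.0, -1.066], [0.0, 0.0, 0.0], [0.0, 0.0, 1.153]]


def _hfh_anion():
    # linear H-F-H anion, F central
    return ["H", "F", "H"], [[0.0, 0.0, -0.97], [0.0, 0.0, 0.0], [0.0, 0.0, 0.97]]


def _hf_pentamer():
    # Planar C5h ring of 5 HF units: 10 atoms on one circle with chords
    # alternating between the F-H bond (0.93 A) and the H...F hydrogen
    # bond (1.80 A).  Half-angles u, v satisfy u + v = pi/5 and
    # a/sin(u) = b/sin(v) = 2R.
    a, b = 0.93, 1.80
    u = brentq(lambda x: math.sin(math.pi / 5.0 - x) / math.sin(x) - b / a,
               1e-6, math.pi / 5.0 - 1e-6)
    radius = a / (2.0 * math.sin(u))
    symbols, coords, ang = [], [], 0.0
    for _ in range(5):
        symbols.append("F")
        coords.append([radius * math.cos(ang), radius * math.sin(ang), 0.0])
        ang += 2.0 * u
        symbols.append("H")
        coords.append([radius * math.cos(ang), radius * math.sin(ang), 0.0])
        ang += 2.0 * (math.pi / 5.0 - u)
    return symbols, coords


def _s8():
    # D4d crown: 8 S on a circle of radius R at alternating heights +-h,
    # solved for S-S 2.05 A and S-S-S angle 108 deg.
    bond, angle = 2.05, math.radians(108.0)

    def place(R, h):
        return np.array([[R * math.cos(k * math.pi / 4.0),
                          R * math.sin(k * math.pi / 4.0),
                          h if k % 2 == 0 else -h] for k in range(8)])

    def eqs(x):
        R, h = x
        p = place(R, h)
        v1, v2 = p[0] - p[1], p[2] - p[1]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return [np.linalg.norm(p[1] - p[0]) - bond, cosang - math.cos(angle)]

    (R, h), = [fsolve(eqs, [2.4, 0.5])]
    coords = place(abs(R), abs(h))
    return ["S"] * 8, coords.tolist()


def _hexamethylenetetramine():
    # Adamantane-like Td cage (CH2)6N4: N on alternating cube vertices
    # (t,t,t)-type, bridging CH2 carbons at (2t,0,0)-type positions.
    # C-N = t*sqrt(3) = 1.47 A; N-C-N angle is exactly tetrahedral.
    cn, ch = 1.47, 1.09
    t = cn / math.sqrt(3.0)
    n_pos = np.array([[t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t]])
    c_pos = np.array([[2 * t, 0, 0], [-2 * t, 0, 0], [0, 2 * t, 0],
                      [0, -2 * t, 0], [0, 0, 2 * t], [0, 0, -2 * t]])
    symbols = ["N"] * 4 + ["C"] * 6
    coords = list(n_pos) + list(c_pos)
    for c in c_pos:
        dn = np.linalg.norm(n_pos - c, axis=1)
        nbrs = n_pos[np.argsort(dn)[:2]]
        u1 = (nbrs[0] - c) / np.linalg.norm(nbrs[0] - c)
        u2 = (nbrs[1] - c) / np.linalg.norm(nbrs[1] - c)
        for hdir in _bridging_h_directions(u1, u2):
            symbols.append("H")
            coords.append(c + ch * hdir)
    return symbols, [list(map(float, c)) for c in coords]


def _acetic_dimer():
    # Planar cyclic dimer (C2h, xy-plane): two O-H...O hydrogen bonds,
    # monomer B = inversion of monomer A through the origin.
    # Carboxyl internals: C=O 1.22, C-O(H) 1.31, C-C 1.50, O-H 0.97,
    # O-C-O 123 deg; hydrogen-bond O...O 2.65.
    co2, coh, cc, oh, ooh = 1.22, 1.31, 1.50, 0.97, 2.65
    half = math.radians(123.0 / 2.0)

    def monomer(d):
        c1 = np.array([d, 0.0, 0.0])
        c2 = c1 + np.array([cc, 0.0, 0.0])
        o1 = c1 + co2 * np.array([-math.cos(half), math.sin(half), 0.0])
        o2 = c1 + coh * np.array([-math.cos(half), -math.sin(half), 0.0])
        return c1, c2, o1, o2

    def gap(d):
        _, _, o1, o2 = monomer(d)
        return np.linalg.norm(o2 - (-o1)) - ooh

    d = brentq(gap, 0.5, 6.0)
    c1, c2, o1, o2 = monomer(d)
    h_acid = o2 + oh * (-o1 - o2) / np.linalg.norm(-o1 - o2)
    u_anti = (c1 - c2) / np.linalg.norm(c1 - c2)
    methyl_h = [c2 + 1.09 * hd for hd in _methyl_h_directions(u_anti)]
    mono_sym = ["C", "C", "O", "O", "H", "H", "H", "H"]
    mono_coords = [c1, c2, o1, o2, h_acid] + methyl_h
    symbols = mono_sym + mono_sym
    coords = [list(map(float, p)) for p in mono_coords]
    coords += [list(map(float, -np.asarray(p))) for p in mono_coords]
    return symbols, coords


_BUILDERS = {
    "benzene": _benzene,
    "s8": _s8,
    "hf_pentamer": _hf_pentamer,
    "hfh_anion": _hfh_anion,
    "acetic_dimer": _acetic_dimer,
    "hexamethylenetetramine": _hexamethylenetetramine,
    "hcn": _hcn,
    "h2": _h2,
}

FIXTURE_NAMES = tuple(sorted(_BUILDERS))


def build_fixture_geometry(name: str) -> FixtureGeometry:
    """Return the named idealized geometry (coordinates in bohr)."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise TopologyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    symbols, coords = builder()
    return FixtureGeometry(name=name, nuclei=_nuclei(symbols, coords))


def read_xyz(source) -> FixtureGeometry:
    """Read a standard XYZ file (count line, comment line, `El x y z` in
    angstrom) into a FixtureGeometry in bohr."""
    if hasattr(source, "read"):
        text = source.read()
        name = "xyz"
    else:
        with open(source, "r", encoding="utf-8") as f:
            text = f.read()
        name = str(source)
    lines = [ln for ln in io.StringIO(text)]
    if len(lines) < 2:
        raise TopologyError("XYZ input truncated: missing header")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise TopologyError("XYZ input: first line must be the atom count") from None
    body = lines[2:2 + n]
    if len(body) < n:
        raise TopologyError(f"XYZ input: expected {n} atom lines, got {len(body)}")
    symbols, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise TopologyError(f"XYZ input: malformed atom line {ln!r}")
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return FixtureGeometry(name=name, nuclei=_nuclei(symbols, coords))
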