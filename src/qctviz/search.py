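"""Critical-point search and gradient-path tracing on an analytic density.

Smooth stationary points (bond, ring and cage CPs) are located by a
batched, damped Newton iteration on the gradient using the analytic
Hessian.  Nuclear attractors are registered directly at the nuclei: an
exponential promolecular density (like the exact density) has a cusp at
each nucleus, so the gradient is attracted to — but never vanishes near —
the nuclear position, and the nucleus itself is the (3,-3) attractor.

Gradient paths are integrated with classic fourth-order Runge-Kutta on
the normalized gradient field (unit speed in arc length), with the step
shrunk geometrically on approach to a CP and a per-step segment-proximity
test so that no close encounter with a CP can be stepped over.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from .density import PromolecularDensity
from .model import (
    INFINITY,
    MERGE_TOL,
    SNAP_TOL,
    ZERO_TOL,
    CriticalPoint,
    GradientPath,
    TopologyError,
    classify_critical_point,
)

log = logging.getLogger(__name__)

#: Nucleus pairs farther apart than this get no midpoint seed (bohr).
SEED_PAIR_CUTOFF = 8.0

#: Maximum RK4 steps per traced path.
MAX_TRACE_STEPS = 100_000


class TracingError(RuntimeError):
    """A gradient-path integration failed to terminate."""


# ----------------------------------------------------------------------
# seeds and Newton search


def default_seeds(density: PromolecularDensity,
                  pair_cutoff: float = SEED_PAIR_CUTOFF) -> np.ndarray:
    """Standard seed set: off-cusp nuclei, midpoints of close pairs, and
    centroids of compact nucleus triples and quadruples."""
    centers = density.centers
    n = len(centers)
    # off-cusp nuclei plus the overall centroid (catches the central ring
    # or cage CP of compact cyclic systems whose diameter exceeds the
    # pair cutoff)
    seeds = [centers + 1e-3, centers.mean(axis=0)[None, :]]
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    for i, j in itertools.combinations(range(n), 2):
        if d[i, j] < pair_cutoff:
            seeds.append((centers[i] + centers[j])[None, :] / 2.0)
    for size in (3, 4):
        for combo in itertools.combinations(range(n), size):
            idx = list(combo)
            if max(d[i, j] for i, j in itertools.combinations(idx, 2)) < pair_cutoff:
                seeds.append(centers[idx].mean(axis=0)[None, :])
    return np.vstack(seeds)


def _newton_batch(density, seeds, newton_tol, max_iter, max_step=0.3):
    """Damped Newton on grad(rho) over a batch of seeds; returns converged
    positions and their gradient norms."""
    centroid, extent = density.centroid(), density.extent()
    r = np.array(seeds, dtype=float)
    active = np.ones(len(r), dtype=bool)
    done_pos, done_gn = [], []
    for _ in range(max_iter):
        if not active.any():
            break
        ra = r[active]
        # points that wandered onto a cusp are discarded
        dist = np.linalg.norm(ra[:, None] - density.centers[None], axis=2)
        on_cusp = dist.min(axis=1) < 1e-6
        if on_cusp.any():
            idx = np.flatnonzero(active)
            active[idx[on_cusp]] = False
            ra = r[active]
            if not len(ra):
                break
        rho, g, h = density.evaluate_batch(ra)
        gn = np.linalg.norm(g, axis=1)
        # Stationarity must hold relative to the local density scale:
        # in the exponential far tail |grad rho| ~ zeta*rho satisfies any
        # absolute threshold without a CP being present.
        conv = (gn < newton_tol) & (gn < 1e-6 * rho)
        idx = np.flatnonzero(active)
        if conv.any():
            done_pos.extend(ra[conv])
            done_gn.extend(gn[conv])
            active[idx[conv]] = False
        keep = ~conv
        if not keep.any():
            continue
        hk, gk = h[keep], g[keep]
        det = np.linalg.det(hk)
        ok = np.abs(det) > 1e-300
        step = np.zeros_like(gk)
        if ok.any():
            step[ok] = np.linalg.solve(hk[ok], -gk[ok][..., None])[..., 0]
        nrm = np.linalg.norm(step, axis=1)
        big = nrm > max_step
        step[big] *= (max_step / nrm[big])[:, None]
        sub = idx[keep]
        r[sub] = r[sub] + step
        escaped = (~ok) | (np.linalg.norm(r[sub] - centroid, axis=1) > extent + 20.0) \
            | ~np.all(np.isfinite(r[sub]), axis=1)
        if escaped.any():
            log.debug("discarding %d diverged Newton seeds", int(escaped.sum()))
            active[sub[escaped]] = False
    return np.array(done_pos).reshape(-1, 3), np.array(done_gn)


def find_critical_points(density: PromolecularDensity,
                         seeds: np.ndarray | None = None,
                         newton_tol: float = 1e-10,
                         max_iter: int = 80,
                         merge_tol: float = MERGE_TOL,
                         zero_tol: float = ZERO_TOL) -> list:
    """Locate and classify all critical points of the density.

    Returns NACPs first (one per nucleus, in nucleus order), then the
    Newton-located saddles/minima sorted by label and position for a
    deterministic ordering.
    """
    if seeds is None:
        seeds = default_seeds(density)
    cps: list[CriticalPoint] = []
    rho_at_nuclei = density.rho(density.centers)
    for nuc, rho in zip(density.nuclei, rho_at_nuclei):
        cps.append(CriticalPoint(position=nuc.position.copy(),
                                 scalars={"rho": float(rho)},
                                 rank=3, signature=-3))
    pos, gn = _newton_batch(density, seeds, newton_tol, max_iter)
    # drop candidates sitting essentially on a nucleus (cusp artifacts)
    if len(pos):
        dnuc = np.linalg.norm(pos[:, None] - density.centers[None], axis=2).min(axis=1)
        keep = dnuc > 10 * merge_tol
        pos, gn = pos[keep], gn[keep]
    # merge duplicates, keeping the smaller |grad rho|
    order = np.argsort(gn, kind="stable")
    kept_pos, kept = [], []
    for i in order:
        p = pos[i]
        if all(np.linalg.norm(p - q) >= merge_tol for q in kept_pos):
            kept_pos.append(p)
            kept.append(i)
    extras = []
    for i in kept:
        rho, g, h = density.evaluate(pos[i])
        evals, evecs = np.linalg.eigh(h)
        rank, signature, label = classify_critical_point(evals, zero_tol)
        extras.append(CriticalPoint(position=pos[i], scalars={"rho": rho},
                                    rank=rank, signature=signature,
                                    eigenvalues=evals, eigenvectors=evecs.T))
    label_order = {"BCP": 0, "RCP": 1, "CCP": 2, "degenerate": 3}
    extras.sort(key=lambda cp: (label_order[cp.label],) + tuple(np.round(cp.position, 6)))
    return cps + extras


# ----------------------------------------------------------------------
# gradient-path tracing


def _decimate(points: np.ndarray, tol: float) -> np.ndarray:
    """Ramer-Douglas-Peucker polyline decimation (max deviation tol)."""
    n = len(points)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        a, b = stack.pop()
        if b <= a + 1:
            continue
        seg = points[b] - points[a]
        length = np.linalg.norm(seg)
        mid = points[a + 1:b] - points[a]
        if length < 1e-300:
            dev = np.linalg.norm(mid, axis=1)
        else:
            dev = np.linalg.norm(np.cross(mid, seg / length), axis=1)
        k = int(np.argmax(dev))
        if dev[k] > tol:
            idx = a + 1 + k
            keep[idx] = True
            stack.append((a, idx))
            stack.append((idx, b))
    return points[keep]


def _segment_point_distance(a: np.ndarray, b: np.ndarray,
                            points: np.ndarray) -> np.ndarray:
    """Distance from each of `points` (N,3) to segment [a, b]."""
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom < 1e-300:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def trace_gradient_path(density: PromolecularDensity,
                        start,
                        direction,
                        orientation: str,
                        cps: list,
                        *,
                        step: float = 0.05,
                        rho_floor: float = 1e-4,
                        snap_tol: float = SNAP_TOL,
                        seed_offset: float = 1e-3,
                        decimation_tol: float = 1e-3,
                        cp_start: int | None = None,
                        max_steps: int = MAX_TRACE_STEPS) -> GradientPath:
    """Integrate one gradient path from `start` seeded along `direction`.

    The path terminates when it passes within ``snap_tol`` of a known CP
    (endpoint snapped onto it) or, for descending paths, when the density
    falls below ``rho_floor`` (``cp_end`` is then the infinity sentinel).
    The start CP is ignored for termination until the path has left its
    0.2-bohr neighbourhood.
    """
    if orientation not in ("ascending", "descending"):
        raise TopologyError(f"orientation must be ascending/descending, "
                            f"got {orientation!r}")
    if step <= 0:
        raise TopologyError("step must be positive")
    sign = 1.0 if orientation == "ascending" else -1.0
    start = np.asarray(start, dtype=float)
    direction = np.asarray(direction, dtype=float)
    dn = np.linalg.norm(direction)
    if dn < 1e-300:
        raise TopologyError("seed direction must be non-zero")
    direction = direction / dn

    cp_pos = np.array([cp.position for cp in cps]).reshape(-1, 3)
    if cp_start is None:
        cp_start = INFINITY
        if len(cp_pos):
            d0 = np.linalg.norm(cp_pos - start, axis=1)
            if d0.min() <= snap_tol:
                cp_start = int(d0.argmin())
    start_excluded = cp_start != INFINITY
    exclude_radius = 0.2

    centroid, extent = density.centroid(), density.extent()
    r = start + seed_offset * direction
    pts = [start.copy(), r.copy()]

    def field(x):
        _, g, _ = density.evaluate(x)
        gn = np.linalg.norm(g)
        if gn < 1e-250:
            raise TracingError("gradient vanished away from any known CP")
        return sign * g / gn

    cp_end = None
    for _ in range(max_steps):
        if start_excluded and np.linalg.norm(r - cp_pos[cp_start]) > exclude_radius:
            start_excluded = False
        mask = np.ones(len(cp_pos), dtype=bool)
        if start_excluded:
            mask[cp_start] = False
        d_near = np.linalg.norm(cp_pos[mask] - r, axis=1).min() if mask.any() else np.inf
        h = min(step, max(0.3 * d_near, 1e-5))
        k1 = field(r)
        k2 = field(r + 0.5 * h * k1)
        k3 = field(r + 0.5 * h * k2)
        k4 = field(r + h * k3)
        r_new = r + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if mask.any():
            dseg = _segment_point_distance(r, r_new, cp_pos[mask])
            jloc = int(dseg.argmin())
            if dseg[jloc] <= snap_tol:
                cp_end = int(np.flatnonzero(mask)[jloc])
                pts.append(cp_pos[cp_end].copy())
                break
        if sign < 0 and float(density.rho(r_new[None])[0]) < rho_floor:
            pts.append(r_new)
            cp_end = INFINITY
            break
        if np.linalg.norm(r_new - centroid) > extent + 20.0:
            if sign < 0:
                pts.append(r_new)
                cp_end = INFINITY
                break
            raise TracingError("ascending path escaped the system bounds")
        pts.append(r_new)
        r = r_new
    if cp_end is None:
        raise TracingError(f"path did not terminate within {max_steps} steps")

    dense = np.array(pts)
    thin = _decimate(dense, decimation_tol)
    # drop duplicate points introduced by snapping
    d = np.linalg.norm(np.diff(thin, axis=0), axis=1)
    keep = np.concatenate([[True], d > 1e-12])
    thin = thin[keep]
    if len(thin) < 2:
        thin = dense[[0, -1]]
    rho_vals = density.rho(thin)
    return GradientPath(points=thin, cp_start=cp_start,
                        cp_end=int(cp_end), scalars={"rho": rho_vals})
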