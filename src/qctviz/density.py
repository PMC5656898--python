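"""Analytic promolecular electron density.

A promolecular density is the sum of spherically symmetric, non-interacting
atomic densities placed at the nuclear positions:

    rho(r) = sum_A sum_i c_i exp(-zeta_i |r - R_A|)

with per-element terms (c_i > 0 au, zeta_i > 0 / bohr) bundled as a
versioned data table (one term per occupied shell group, normalized so
each shell integrates to its electron count).  The field is positive
everywhere, has closed-form gradient and Hessian away from the nuclei,
and carries the same topological object vocabulary as a molecular ab
initio density — which makes it a fast, fully analytic generator of
complete synthetic topologies.

Note the nuclear cusps: like the exact density, a promolecular exponential
sum is non-differentiable at each nucleus, where |grad rho| tends to a
finite non-zero limit.  Nuclei are therefore attractors of the gradient
field without being smooth stationary points; see :mod:`qctviz.search`.
"""

from __future__ import annotations

import numpy as np

from .elements import promolecular_terms
from .model import Nucleus, TopologyError

#: Evaluation closer to a nucleus than this raises (gradient undefined).
CUSP_TOL = 1e-10


class PromolecularDensity:
    """Promolecular density for a set of nuclei.

    Parameters
    ----------
    nuclei : list of Nucleus
        Positions in bohr.
    terms : dict, optional
        Mapping element symbol -> list of ``(c, zeta)`` pairs; defaults to
        the bundled shell-resolved table.
    """

    def __init__(self, nuclei: list, terms: dict | None = None):
        if not nuclei:
            raise TopologyError("need at least one nucleus")
        self.nuclei = list(nuclei)
        table = terms if terms is not None else {
            sym: [(t["c"], t["zeta"]) for t in entry["terms"]]
            for sym, entry in promolecular_terms().items()}
        self.centers = np.array([n.position for n in nuclei], dtype=float)
        c, zeta, owner = [], [], []
        for ai, n in enumerate(self.nuclei):
            if n.element not in table:
                raise TopologyError(
                    f"no promolecular terms for element {n.element!r}")
            for ci, zi in table[n.element]:
                if not (ci > 0 and zi > 0):
                    raise TopologyError("term coefficients/exponents must be positive")
                c.append(ci)
                zeta.append(zi)
                owner.append(ai)
        self._c = np.asarray(c)           # (T,)
        self._zeta = np.asarray(zeta)     # (T,)
        self._owner = np.asarray(owner)   # (T,) nucleus index per term

    # -- geometry helpers ----------------------------------------------

    def extent(self) -> float:
        """Radius of the nuclear bounding sphere about the centroid (bohr)."""
        centroid = self.centers.mean(axis=0)
        return float(np.max(np.linalg.norm(self.centers - centroid, axis=1)))

    def centroid(self) -> np.ndarray:
        return self.centers.mean(axis=0)

    # -- evaluation ----------------------------------------------------

    def rho(self, points: np.ndarray) -> np.ndarray:
        """Density only, vectorized: points (..., 3) -> rho (...,).

        Valid everywhere including exactly at nuclei (the density itself
        is continuous through the cusps).
        """
        pts = np.asarray(points, dtype=float)
        shape = pts.shape[:-1]
        flat = pts.reshape(-1, 3)
        d = np.linalg.norm(flat[:, None, :] - self.centers[None, :, :], axis=2)
        val = np.einsum("t,st->s", self._c, np.exp(-self._zeta * d[:, self._owner]))
        return val.reshape(shape)

    def evaluate(self, r) -> tuple[float, np.ndarray, np.ndarray]:
        """Density, gradient and Hessian at a single point.

        Raises if ``r`` is within :data:`CUSP_TOL` of a nucleus, where the
        derivatives are undefined.
        """
        rho, grad, hess = self.evaluate_batch(np.asarray(r, dtype=float)[None, :])
        return float(rho[0]), grad[0], hess[0]

    def evaluate_batch(self, points: np.ndarray):
        """Vectorized (rho, grad, Hessian) at points of shape (S, 3).

        For a radial term f(d) = c exp(-zeta d):
            grad = f'(d) u                       with u = (r - R)/d
            H    = f''(d) u u^T + (f'(d)/d) (I - u u^T)
        """
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise TopologyError("expected points of shape (S, 3)")
        if not np.all(np.isfinite(pts)):
            raise TopologyError("non-finite evaluation point")
        diff = pts[:, None, :] - self.centers[None, :, :]        # (S, M, 3)
        dist = np.linalg.norm(diff, axis=2)                      # (S, M)
        if np.any(dist < CUSP_TOL):
            raise TopologyError(
                f"evaluation point within {CUSP_TOL} bohr of a nucleus (cusp)")
        d = dist[:, self._owner]                                  # (S, T)
        u = diff[:, self._owner, :] / d[..., None]                # (S, T, 3)
        f = self._c * np.exp(-self._zeta * d)                     # (S, T)
        fp = -self._zeta * f
        fpp = self._zeta ** 2 * f
        rho = f.sum(axis=1)
        grad = np.einsum("st,stx->sx", fp, u)
        uu = np.einsum("stx,sty->stxy", u, u)                     # (S, T, 3, 3)
        eye = np.eye(3)
        hess = (np.einsum("st,stxy->sxy", fpp, uu)
                + np.einsum("st,stxy->sxy", fp / d, eye[None, None] - uu))
        return rho, grad, hess

    def grad_norm(self, r) -> float:
        _, g, _ = self.evaluate(r)
        return float(np.linalg.norm(g))
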