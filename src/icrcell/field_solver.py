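"""Numeric Dirichlet-Laplace solver on axisymmetric (rho, z) and Cartesian 3-D grids.

The axisymmetric stencil discretizes phi_rr + phi_r/rho + phi_zz with the
rho = 0 axis handled by symmetry (the limiting form 2 phi_rr).  Three methods
are available:

* ``direct`` -- sparse LU factorization of the 5-point system (2-D default);
* ``cg``     -- conjugate gradients on the symmetric 7-point system (3-D default);
* ``sor``    -- red-black successive over-relaxation, the classical relaxation
  scheme; kept as an independent reference implementation and for grids where
  assembling the sparse operator is not worthwhile.

Converged solutions satisfy the discrete maximum principle: the extrema of
phi are attained on Dirichlet nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .trap_geometry import BoundaryGrid

__all__ = ["PotentialGrid", "solve", "refine_study"]


@dataclass
class PotentialGrid:
    """Solved potential on the grid of a :class:`BoundaryGrid`."""

    axes: tuple[np.ndarray, ...]
    phi: np.ndarray
    dirichlet_mask: np.ndarray
    axisymmetric: bool
    converged: bool
    residual: float
    iterations: int = 0

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(float(a[1] - a[0]) for a in self.axes)


class DivergenceError(RuntimeError):
    pass


def _check_closed(boundary: BoundaryGrid) -> None:
    mask = boundary.dirichlet_mask
    for ax in range(mask.ndim):
        for side in (0, -1):
            if boundary.axisymmetric and ax == 0 and side == 0:
                continue
            sl = [slice(None)] * mask.ndim
            sl[ax] = side
            if not mask[tuple(sl)].all():
                raise ValueError("open boundary: the outer box is not closed")


def _assemble_axisym(boundary: BoundaryGrid):
    rho, zax = boundary.axes
    hr, hz = boundary.spacing
    mask = boundary.dirichlet_mask
    val = boundary.dirichlet_value
    nr, nz = mask.shape
    n = nr * nz

    def node(i, j):
        return i * nz + j

    I, J = np.meshgrid(np.arange(nr), np.arange(nz), indexing="ij")
    I = I.ravel(); J = J.ravel()
    fixed = mask.ravel()
    rows, cols, data = [], [], []
    b = np.zeros(n)
    d = np.nonzero(fixed)[0]
    rows.append(d); cols.append(d); data.append(np.ones(d.size))
    b[d] = val.ravel()[d]

    f = ~fixed
    fI, fJ = I[f], J[f]
    me = node(fI, fJ)
    r = rho[fI]
    ax = fI == 0
    rows.append(me); cols.append(me)
    data.append(np.where(ax, -4.0 / hr**2, -2.0 / hr**2) - 2.0 / hz**2)
    wp = np.where(ax, 4.0 / hr**2, 1.0 / hr**2 + 1.0 / (2 * np.where(ax, 1.0, r) * hr))
    rows.append(me); cols.append(node(fI + 1, fJ)); data.append(wp)
    nm = ~ax
    wm = 1.0 / hr**2 - 1.0 / (2 * r[nm] * hr)
    rows.append(me[nm]); cols.append(node(fI[nm] - 1, fJ[nm])); data.append(wm)
    for dj in (-1, 1):
        rows.append(me); cols.append(node(fI, fJ + dj))
        data.append(np.full(me.size, 1.0 / hz**2))
    A = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    return A, b, f


def _assemble_cart3d(boundary: BoundaryGrid):
    mask = boundary.dirichlet_mask
    val = boundary.dirichlet_value
    shape = mask.shape
    h = boundary.spacing
    free = ~mask
    n = int(free.sum())
    idx = -np.ones(shape, np.int64)
    idx[free] = np.arange(n)
    fi = np.argwhere(free)
    diag = 2.0 * sum(1.0 / hh**2 for hh in h)
    rows = [np.arange(n)]; cols = [np.arange(n)]; data = [np.full(n, diag)]
    b = np.zeros(n)
    for ax in range(3):
        w = 1.0 / h[ax] ** 2
        for s in (-1, 1):
            nb = fi.copy()
            nb[:, ax] += s
            if (nb[:, ax] < 0).any() or (nb[:, ax] >= shape[ax]).any():
                raise ValueError("open boundary: free node on the box face")
            j = idx[nb[:, 0], nb[:, 1], nb[:, 2]]
            isfree = j >= 0
            rows.append(np.arange(n)[isfree]); cols.append(j[isfree])
            data.append(np.full(int(isfree.sum()), -w))
            vb = val[nb[~isfree, 0], nb[~isfree, 1], nb[~isfree, 2]]
            np.add.at(b, np.arange(n)[~isfree], w * vb)
    A = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    return A, b, free


def _residual_axisym(boundary: BoundaryGrid, phi: np.ndarray) -> float:
    """Max |stencil defect| on free nodes, in volts (h^2-scaled)."""
    rho, _ = boundary.axes
    hr, hz = boundary.spacing
    free = ~boundary.dirichlet_mask
    inner = free[1:-1, 1:-1]
    r = rho[1:-1][:, None]
    lap = ((phi[2:, 1:-1] - 2 * phi[1:-1, 1:-1] + phi[:-2, 1:-1]) / hr**2
           + (phi[2:, 1:-1] - phi[:-2, 1:-1]) / (2 * r * hr)
           + (phi[1:-1, 2:] - 2 * phi[1:-1, 1:-1] + phi[1:-1, :-2]) / hz**2)
    scale = 2.0 / hr**2 + 2.0 / hz**2
    worst = np.abs(lap[inner]).max() / scale if inner.any() else 0.0
    # axis row (rho = 0): symmetric limit
    ax_free = free[0, 1:-1]
    if ax_free.any():
        lap0 = (4 * (phi[1, 1:-1] - phi[0, 1:-1]) / hr**2
                + (phi[0, 2:] - 2 * phi[0, 1:-1] + phi[0, :-2]) / hz**2)
        worst = max(worst, np.abs(lap0[ax_free]).max() / (4.0 / hr**2 + 2.0 / hz**2))
    return float(worst)


def _residual_cart3d(boundary: BoundaryGrid, phi: np.ndarray) -> float:
    h = boundary.spacing
    free = ~boundary.dirichlet_mask
    inner = free[1:-1, 1:-1, 1:-1]
    if not inner.any():
        return 0.0
    c = phi[1:-1, 1:-1, 1:-1]
    lap = ((phi[2:, 1:-1, 1:-1] - 2 * c + phi[:-2, 1:-1, 1:-1]) / h[0]**2
           + (phi[1:-1, 2:, 1:-1] - 2 * c + phi[1:-1, :-2, 1:-1]) / h[1]**2
           + (phi[1:-1, 1:-1, 2:] - 2 * c + phi[1:-1, 1:-1, :-2]) / h[2]**2)
    scale = 2.0 * sum(1.0 / hh**2 for hh in h)
    return float(np.abs(lap[inner]).max() / scale)


def _sor_axisym(boundary: BoundaryGrid, tol, max_iter, omega):
    rho, _ = boundary.axes
    hr, hz = boundary.spacing
    mask = boundary.dirichlet_mask
    phi = boundary.dirichlet_value.copy()
    nr, nz = mask.shape
    if omega is None:
        omega = 2.0 / (1.0 + np.sin(np.pi / max(nr, nz)))
    I, J = np.meshgrid(np.arange(nr), np.arange(nz), indexing="ij")
    r = rho[:, None] + np.zeros((1, nz))
    ax = r == 0
    cdiag = np.where(ax, 4.0 / hr**2, 2.0 / hr**2) + 2.0 / hz**2
    wp = np.where(ax, 4.0 / hr**2, 1.0 / hr**2 + 1.0 / (2 * np.where(ax, 1.0, r) * hr))
    wm = np.where(ax, 0.0, 1.0 / hr**2 - 1.0 / (2 * np.where(ax, 1.0, r) * hr))
    free = ~mask
    history = []
    it = 0
    for it in range(1, max_iter + 1):
        for parity in (0, 1):
            upd = free & (((I + J) % 2) == parity)
            up = np.zeros_like(phi); dn = np.zeros_like(phi)
            up[:-1] = phi[1:]
            dn[1:] = phi[:-1]
            left = np.zeros_like(phi); right = np.zeros_like(phi)
            left[:, 1:] = phi[:, :-1]
            right[:, :-1] = phi[:, 1:]
            gs = (wp * up + wm * dn + (left + right) / hz**2) / cdiag
            phi[upd] += omega * (gs[upd] - phi[upd])
        if it % 20 == 0 or it == max_iter:
            res = _residual_axisym(boundary, phi)
            history.append(res)
            if res <= tol:
                return phi, True, res, it
            if len(history) > 5 and history[-1] > 10 * min(history):
                raise DivergenceError(f"residual growing after {it} sweeps")
    return phi, False, _residual_axisym(boundary, phi), it


def _sor_cart3d(boundary: BoundaryGrid, tol, max_iter, omega):
    mask = boundary.dirichlet_mask
    h = boundary.spacing
    phi = boundary.dirichlet_value.copy()
    shape = mask.shape
    if omega is None:
        omega = 2.0 / (1.0 + np.sin(np.pi / max(shape)))
    wx, wy, wz = (1.0 / hh**2 for hh in h)
    cdiag = 2.0 * (wx + wy + wz)
    I, J, K = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    parity_idx = (I + J + K) % 2
    free = ~mask
    it = 0
    for it in range(1, max_iter + 1):
        for parity in (0, 1):
            upd = free & (parity_idx == parity)
            gs = np.zeros_like(phi)
            gs[1:-1, 1:-1, 1:-1] = (
                wx * (phi[2:, 1:-1, 1:-1] + phi[:-2, 1:-1, 1:-1])
                + wy * (phi[1:-1, 2:, 1:-1] + phi[1:-1, :-2, 1:-1])
                + wz * (phi[1:-1, 1:-1, 2:] + phi[1:-1, 1:-1, :-2])) / cdiag
            phi[upd] += omega * (gs[upd] - phi[upd])
        if it % 20 == 0 or it == max_iter:
            res = _residual_cart3d(boundary, phi)
            if res <= tol:
                return phi, True, res, it
    return phi, False, _residual_cart3d(boundary, phi), it


def solve(boundary: BoundaryGrid, tol: float = 1e-10, max_iter: int = 20000,
          method: str = "auto", omega: float | None = None) -> PotentialGrid:
    """Solve the Dirichlet-Laplace problem of ``boundary``.

    ``tol`` is the residual target in volts (maximum h^2-scaled stencil
    defect over free nodes).  ``method`` is ``direct``, ``cg``, ``sor`` or
    ``auto`` (direct for 2-D, cg for 3-D).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    _check_closed(boundary)
    mask = boundary.dirichlet_mask
    if method == "auto":
        method = "direct" if mask.ndim == 2 else "cg"

    if method == "sor":
        fn = _sor_axisym if mask.ndim == 2 else _sor_cart3d
        phi, ok, res, it = fn(boundary, tol, max_iter, omega)
        return PotentialGrid(boundary.axes, phi, mask, boundary.axisymmetric,
                             ok, res, it)

    if mask.ndim == 2:
        A, b, free_flat = _assemble_axisym(boundary)
        phi_flat = spla.spsolve(A.tocsc(), b)
        phi = phi_flat.reshape(mask.shape)
        res = _residual_axisym(boundary, phi)
        return PotentialGrid(boundary.axes, phi, mask, boundary.axisymmetric,
                             res <= max(tol, 1e-9 * max(1.0, np.abs(b).max())),
                             res, 1)

    if method == "direct":
        raise ValueError("direct factorization is not supported for 3-D grids; use cg")
    A, b, free = _assemble_cart3d(boundary)
    x0 = np.full(A.shape[0], float(boundary.dirichlet_value[mask].mean()))
    x, info = spla.cg(A, b, x0=x0, rtol=1e-12, atol=0.0, maxiter=max_iter)
    phi = boundary.dirichlet_value.copy()
    phi[free] = x
    res = _residual_cart3d(boundary, phi)
    ok = info == 0 and res <= max(tol, 1e-8 * max(1.0, np.abs(b).max()))
    return PotentialGrid(boundary.axes, phi, mask, boundary.axisymmetric, ok, res, 1)


def refine_study(make_boundary, spacings: list[float], fit, **solve_kw):
    """Fitted coefficients versus grid spacing (convergence report).

    ``make_boundary(spacing)`` builds the Dirichlet problem, ``fit(PotentialGrid)``
    returns the quantity of interest (e.g. a HarmonicFit).  At least three
    spacings in (roughly) geometric progression are required.
    """
    if len(spacings) < 3:
        raise ValueError("need >= 3 spacings for a convergence study")
    out = []
    for h in spacings:
        grid = solve(make_boundary(h), **solve_kw)
        out.append((h, fit(grid)))
    return out
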