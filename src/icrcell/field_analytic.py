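"""Closed-form and series potentials for the analytically solvable cells.

These serve both as standalone field sources for the evaluation pipeline and
as independent oracles for the numeric Laplace solver:

* ideal (harmonic) field  alpha (z^2 - rho^2/2) + chi;
* rectangular-box (cuboid/cubic) trapping series and its exact azimuthal
  average (the angular mean of cos(ax)cos(by) over a circle of radius rho is
  J0(rho sqrt(a^2+b^2)));
* closed-cylinder trapping series (modified-Bessel modes) and the dipolar
  excitation series; rectangular-box dipolar series;
* dynamically harmonized cell ("paracell"): the exact per-slice disk
  harmonic-measure solution for the full theta-dependent potential and the
  closed-form azimuthally averaged potential;
* compensation-electrode sensitivities V0 dA_k/dV_c of the closed
  compensated cylinder from the eigenfunction expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import i0e, ive, j0

from .trap_geometry import TrapGeometry, paracell_leaf_halfwidth

__all__ = [
    "IdealFieldParams", "SeriesTruncation", "CenterExpansion",
    "SeriesConvergenceError",
    "harmonic_basis", "harmonic_series_potential", "ideal_potential",
    "cuboid_potential", "cuboid_averaged", "cylinder_potential",
    "cubic_dipolar_potential", "cylinder_dipolar_potential",
    "paracell_full_potential", "paracell_averaged_potential",
    "trapping_potential", "excitation_potential", "center_expansion",
    "compensated_sensitivity", "paracell_average_consistency",
]


@dataclass(frozen=True)
class IdealFieldParams:
    """Harmonic trapping field alpha (z^2 - rho^2/2) + chi."""
    alpha: float  # V/m^2
    chi: float = 0.0  # V


@dataclass(frozen=True)
class SeriesTruncation:
    max_terms: int = 500
    tol: float = 1e-12  # absolute tail tolerance, in units of the driving voltage

    def __post_init__(self):
        if self.max_terms < 1 or self.tol <= 0:
            raise ValueError("max_terms >= 1 and tol > 0 required")


@dataclass(frozen=True)
class CenterExpansion:
    """Near-centre expansion V = V_ref [gamma + (alpha_coef/a^2)(z^2 - rho^2/2)].

    ``a`` is the full cell dimension (edge for the box, 2R for the cylinder).
    """
    gamma: float
    alpha_coef: float
    a: float


class SeriesConvergenceError(RuntimeError):
    def __init__(self, achieved: float, requested: float):
        self.achieved = achieved
        self.requested = requested
        super().__init__(
            f"series not converged: tail bound {achieved:.3e} > requested {requested:.3e}")


_DEFAULT_TRUNC = SeriesTruncation()


def harmonic_basis(rho, z):
    """The four axisymmetric even-harmonic basis functions (orders 0, 2, 4, 6)."""
    rho = np.asarray(rho, float)
    z = np.asarray(z, float)
    return (
        np.ones(np.broadcast(rho, z).shape),
        z**2 - rho**2 / 2,
        8 * z**4 - 24 * z**2 * rho**2 + 3 * rho**4,
        16 * z**6 - 120 * z**4 * rho**2 + 90 * z**2 * rho**4 - 5 * rho**6,
    )


def harmonic_series_potential(rho, z, C=0.0, A20=0.0, A40=0.0, A60=0.0):
    """Synthetic potential with prescribed harmonic content (test fixture source)."""
    b0, b2, b4, b6 = harmonic_basis(rho, z)
    return C * b0 + A20 * b2 + A40 * b4 + A60 * b6


def ideal_potential(rho, z, params: IdealFieldParams):
    rho = np.asarray(rho, float); z = np.asarray(z, float)
    return params.alpha * (z**2 - rho**2 / 2) + params.chi


# ---------------------------------------------------------------------------
# rectangular box
# ---------------------------------------------------------------------------


def _cosh_ratio(k, z, half):
    """cosh(k z)/cosh(k half), overflow-safe for large k."""
    z = np.abs(z)
    return np.exp(k * (z - half)) * (1 + np.exp(-2 * k * z)) / (1 + np.exp(-2 * k * half))


def cuboid_potential(x, y, z, a, b, c, v_trap, v_other=0.0,
                     trunc: SeriesTruncation = _DEFAULT_TRUNC):
    """Trapping potential inside an a x b x c box, plates at z = +/- c/2 at v_trap."""
    x = np.asarray(x, float); y = np.asarray(y, float); z = np.asarray(z, float)
    out = np.full(np.broadcast(x, y, z).shape, float(v_other))
    pref = 16 / np.pi**2 * (v_trap - v_other)
    zmax = np.max(np.abs(z))
    tail = np.inf
    for m in range(trunc.max_terms):
        row_max = 0.0
        for n in range(trunc.max_terms):
            al = (2 * m + 1) * np.pi / a
            be = (2 * n + 1) * np.pi / b
            k = math.hypot(al, be)
            amp = abs(pref) * _cosh_ratio(k, zmax, c / 2) / ((2 * m + 1) * (2 * n + 1))
            if amp < trunc.tol * max(abs(v_trap - v_other), 1e-300) and n > 0:
                break
            row_max = max(row_max, amp)
            out = out + (pref * (-1) ** (m + n) * _cosh_ratio(k, z, c / 2)
                         * np.cos(al * x) * np.cos(be * y)
                         / ((2 * m + 1) * (2 * n + 1)))
        tail = row_max
        if row_max < trunc.tol * max(abs(v_trap - v_other), 1e-300) and m > 0:
            return out
    if tail > 100 * trunc.tol * max(abs(v_trap - v_other), 1e-300):
        raise SeriesConvergenceError(tail, trunc.tol * abs(v_trap - v_other))
    return out


def cuboid_averaged(rho, z, a, b, c, v_trap, v_other=0.0,
                    trunc: SeriesTruncation = _DEFAULT_TRUNC):
    """Exact azimuthal average of the box trapping potential (J0-weighted series)."""
    rho = np.asarray(rho, float); z = np.asarray(z, float)
    out = np.full(np.broadcast(rho, z).shape, float(v_other))
    pref = 16 / np.pi**2 * (v_trap - v_other)
    zmax = np.max(np.abs(z))
    scale = max(abs(v_trap - v_other), 1e-300)
    for m in range(trunc.max_terms):
        row_max = 0.0
        for n in range(trunc.max_terms):
            al = (2 * m + 1) * np.pi / a
            be = (2 * n + 1) * np.pi / b
            k = math.hypot(al, be)
            amp = abs(pref) * _cosh_ratio(k, zmax, c / 2) / ((2 * m + 1) * (2 * n + 1))
            if amp < trunc.tol * scale and n > 0:
                break
            row_max = max(row_max, amp)
            out = out + (pref * (-1) ** (m + n) * _cosh_ratio(k, z, c / 2)
                         * j0(rho * k) / ((2 * m + 1) * (2 * n + 1)))
        if row_max < trunc.tol * scale and m > 0:
            break
    return out


def cubic_dipolar_potential(x, y, z, a, v_dipolar,
                            trunc: SeriesTruncation = _DEFAULT_TRUNC):
    """Dipolar excitation potential of the cubic cell (plates x = +/- a/2 at +/- V/2)."""
    x = np.asarray(x, float); y = np.asarray(y, float); z = np.asarray(z, float)
    out = np.zeros(np.broadcast(x, y, z).shape)
    pref = 16 / np.pi**2 * (v_dipolar / 2)
    xmax = np.max(np.abs(x))
    scale = max(abs(v_dipolar), 1e-300)
    for m in range(trunc.max_terms):
        row_max = 0.0
        for n in range(trunc.max_terms):
            al = (2 * m + 1) * np.pi / a
            be = (2 * n + 1) * np.pi / a
            k = math.hypot(al, be)
            amp = abs(pref) * _cosh_ratio(k, xmax, a / 2) / ((2 * m + 1) * (2 * n + 1))
            if amp < trunc.tol * scale and n > 0:
                break
            row_max = max(row_max, amp)
            # sinh(kx)/sinh(k a/2), overflow-safe
            ratio = (np.exp(k * (np.abs(x) - a / 2)) * (1 - np.exp(-2 * k * np.abs(x)))
                     / (1 - np.exp(-k * a)))
            out = out + (pref * (-1) ** (m + n) * np.sign(x) * ratio
                         * np.cos(al * y) * np.cos(be * z)
                         / ((2 * m + 1) * (2 * n + 1)))
        if row_max < trunc.tol * scale and m > 0:
            break
    return out


# ---------------------------------------------------------------------------
# closed cylinder
# ---------------------------------------------------------------------------


def cylinder_potential(rho, z, R, z0, v_trap,
                       trunc: SeriesTruncation = _DEFAULT_TRUNC):
    """Trapping potential of the closed cylinder (end caps at v_trap, wall 0)."""
    rho = np.asarray(rho, float); z = np.asarray(z, float)
    out = np.full(np.broadcast(rho, z).shape, float(v_trap))
    scale = max(abs(v_trap), 1e-300)
    rho_max = np.max(rho)
    for idx in range(trunc.max_terms):
        j = 2 * idx + 1
        g = j * np.pi / (2 * z0)
        coef = 4 * math.sin(j * math.pi / 2) / (math.pi * j)
        rad = i0e(g * rho) / i0e(g * R) * np.exp(g * (rho - R))
        out = out - v_trap * coef * rad * np.cos(g * z)
        amp = abs(v_trap) * 4 / (math.pi * j) * i0e(g * rho_max) / i0e(g * R) * math.exp(g * (rho_max - R))
        if amp < trunc.tol * scale and idx > 2:
            return out
    if amp > 100 * trunc.tol * scale:
        raise SeriesConvergenceError(amp, trunc.tol * scale)
    return out


def cylinder_dipolar_potential(rho, theta, z, R, z0, v_e,
                               trunc: SeriesTruncation = _DEFAULT_TRUNC):
    """Dipolar excitation potential of the closed cylinder.

    Excitation electrodes are 90-degree wall sectors centred on +/- x held at
    +/- v_e; end caps and the remaining wall grounded.
    """
    rho = np.asarray(rho, float); theta = np.asarray(theta, float)
    z = np.asarray(z, float)
    out = np.zeros(np.broadcast(rho, theta, z).shape)
    scale = max(abs(v_e), 1e-300)
    rho_max = float(np.max(rho))
    for mi in range(trunc.max_terms):
        m = 2 * mi + 1
        s4 = math.sin(m * math.pi / 4)
        if s4 == 0.0:
            continue
        row_max = 0.0
        for ki in range(trunc.max_terms):
            k = 2 * ki + 1
            g = k * np.pi / (2 * z0)
            coef = (16 * s4 * math.sin(k * math.pi / 2)
                    / (np.pi**2 * m * k))
            rad = ive(m, g * rho) / ive(m, g * R) * np.exp(g * (rho - R))
            out = out + v_e * coef * rad * np.cos(m * theta) * np.cos(g * z)
            amp = (abs(v_e) * 16 / (np.pi**2 * m * k)
                   * ive(m, g * rho_max) / ive(m, g * R) * math.exp(g * (rho_max - R)))
            row_max = max(row_max, amp)
            if amp < trunc.tol * scale and ki > 2:
                break
        if row_max < trunc.tol * scale and mi > 2:
            break
    return out


# ---------------------------------------------------------------------------
# dynamically harmonized cell
# ---------------------------------------------------------------------------


def _arc_harmonic_measure(w, R, a, b):
    """Harmonic measure of the boundary arc (a, b) of the disk |w| < R.

    omega = arg[(R e^{ib} - w)/(R e^{ia} - w)] / pi - (b - a)/(2 pi), with the
    argument taken in [0, 2 pi); equals the mean-value weight of the arc.
    """
    num = R * np.exp(1j * b) - w
    den = R * np.exp(1j * a) - w
    ang = np.mod(np.angle(num / den), 2 * np.pi)
    return ang / np.pi - (b - a) / (2 * np.pi)


def paracell_full_potential(rho, theta, z, R, z0, N, beta, phi0):
    """Full theta-dependent paracell potential (per-slice disk solution).

    At each height z the wall pattern (grounded leaves / biased sectors from
    the z^2-modulated leaf shape) is propagated into the cross-section as the
    exact 2-D harmonic extension; the quadratic first term carries the axial
    curvature.  This reproduces the structure of the published closed-form
    approximation; it is not an exact 3-D solution but is accurate in the
    working volume.
    """
    rho = np.asarray(rho, float); theta = np.asarray(theta, float)
    z = np.asarray(z, float)
    w = rho * np.exp(1j * theta)
    halfw = paracell_leaf_halfwidth(z, z0, N, beta)
    out = beta * phi0 * (R**2 - rho**2) / (2 * z0**2)
    acc = np.zeros(np.broadcast(rho, theta, z).shape)
    for n in range(N):
        a = np.pi / N * (2 * n) + halfw
        b = np.pi / N * (2 * n + 2) - halfw
        acc = acc + _arc_harmonic_measure(w, R, a, b)
    return out + phi0 * acc


def paracell_averaged_potential(rho, z, R, z0, beta, phi0):
    """Azimuthally averaged paracell potential (closed form, exactly harmonic)."""
    rho = np.asarray(rho, float); z = np.asarray(z, float)
    return (phi0 * (1.0 - beta * (1.0 - z**2 / z0**2))
            + beta * phi0 * (R**2 - rho**2) / (2 * z0**2))


def paracell_average_consistency(geometry: TrapGeometry,
                                 trunc: SeriesTruncation = _DEFAULT_TRUNC,
                                 n_theta: int = 1024) -> dict:
    """Discrepancy between the theta-quadrature of the full potential and the
    closed-form average, over a test grid; resolves the averaged-form ambiguity."""
    p = geometry.params
    R, z0, N, beta, phi0 = p["R"], p["z0"], p["N"], p["beta"], p["v_trap"]
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    rr = np.linspace(0, 0.95 * R, 13)
    zz = np.linspace(-0.9 * z0, 0.9 * z0, 17)
    Rg, Zg, Tg = np.meshgrid(rr, zz, theta, indexing="ij")
    full = paracell_full_potential(Rg, Tg, Zg, R, z0, N, beta, phi0).mean(axis=2)
    avg = paracell_averaged_potential(rr[:, None], zz[None, :], R, z0, beta, phi0)
    diff = np.abs(full - avg)
    return {
        "max": float(diff.max()),
        "on_axis_max": float(diff[0, :].max()),
        "near_wall_max": float(diff[-1, :].max()),
    }


# ---------------------------------------------------------------------------
# compensated-cylinder sensitivities
# ---------------------------------------------------------------------------


def compensated_sensitivity(R: float, z0: float, dz_c: float, k: int,
                            trunc: SeriesTruncation = _DEFAULT_TRUNC) -> float:
    """V0 dA_k/dV_c for the closed compensated cylinder (dimensionless).

    Convention phi = (1/2) V0 sum_k A_k (r/d)^k P_k(cos theta) with
    d^2 = (1/2)(z0^2 + R^2/2).  The compensation electrodes are the wall
    bands z in +/- [z0 - dz_c, z0].  Eigenfunction expansion: modes
    cos(lambda_j z) I0(lambda_j rho), lambda_j = (j - 1/2) pi / z0, with
    Fourier weights 2 (-1)^{j+1} (1 - cos(lambda_j dz_c)) / (lambda_j z0).
    """
    if k < 2 or k % 2:
        raise ValueError("k must be even and >= 2")
    if not (0 < dz_c < 2 * z0):
        raise ValueError("0 < dz_c < 2 z0 required")
    d = math.sqrt(0.5 * (z0**2 + 0.5 * R**2))
    total = 0.0
    for j in range(1, trunc.max_terms + 1):
        lam = (j - 0.5) * math.pi / z0
        fourier = 2.0 * (-1) ** (j + 1) * (1.0 - math.cos(lam * dz_c)) / (lam * z0)
        term = (2.0 * d**k * (-1) ** (k // 2) / math.factorial(k)
                * fourier * lam**k / (i0e(lam * R) * math.exp(lam * R)))
        total += term
        if j > 3 and abs(term) < trunc.tol * max(abs(total), 1e-30):
            return total
    raise SeriesConvergenceError(abs(term), trunc.tol * max(abs(total), 1e-30))


# ---------------------------------------------------------------------------
# dispatch interfaces
# ---------------------------------------------------------------------------


def _pt(point):
    point = np.asarray(point, float)
    return point[..., 0], point[..., 1], point[..., 2]


def trapping_potential(kind: str, geometry, point,
                       trunc: SeriesTruncation = _DEFAULT_TRUNC):
    """Trapping potential at ``point`` (x, y, z in metres; batch-capable)."""
    x, y, z = _pt(point)
    rho = np.hypot(x, y)
    if kind == "ideal":
        if not isinstance(geometry, IdealFieldParams):
            raise TypeError("ideal field takes IdealFieldParams")
        return ideal_potential(rho, z, geometry)
    p = geometry.params
    if kind in ("cuboid", "cubic"):
        a = p["a"]; b = p.get("b", a); c = p.get("c", a)
        if np.any((np.abs(x) > a / 2) | (np.abs(y) > b / 2) | (np.abs(z) > c / 2)):
            raise ValueError("point outside the cell")
        return cuboid_potential(x, y, z, a, b, c, p["v_trap"], trunc=trunc)
    if kind == "cylindrical":
        if np.any((rho > p["R"]) | (np.abs(z) > p["z0"])):
            raise ValueError("point outside the cell")
        return cylinder_potential(rho, z, p["R"], p["z0"], p["v_trap"], trunc=trunc)
    if kind in ("paracell_averaged", "paracell_full"):
        if np.any((rho > p["R"]) | (np.abs(z) > p["z0"])):
            raise ValueError("point outside the cell")
        if kind == "paracell_averaged":
            return paracell_averaged_potential(rho, z, p["R"], p["z0"],
                                               p["beta"], p["v_trap"])
        theta = np.arctan2(y, x)
        return paracell_full_potential(rho, theta, z, p["R"], p["z0"],
                                       p["N"], p["beta"], p["v_trap"])
    raise ValueError(f"unknown analytic trapping kind {kind!r}")


def excitation_potential(kind: str, geometry, point,
                         trunc: SeriesTruncation = _DEFAULT_TRUNC,
                         v_dipolar: float = 1.0):
    """Dipolar excitation potential at ``point`` (odd in x)."""
    x, y, z = _pt(point)
    p = geometry.params
    if kind == "cubic_dipolar":
        a = p["a"]
        if np.any((np.abs(x) > a / 2) | (np.abs(y) > a / 2) | (np.abs(z) > a / 2)):
            raise ValueError("point outside the cell")
        return cubic_dipolar_potential(x, y, z, a, v_dipolar, trunc=trunc)
    if kind == "cylindrical_dipolar":
        rho = np.hypot(x, y)
        if np.any((rho > p["R"]) | (np.abs(z) > p["z0"])):
            raise ValueError("point outside the cell")
        theta = np.arctan2(y, x)
        return cylinder_dipolar_potential(rho, theta, z, p["R"], p["z0"],
                                          v_dipolar, trunc=trunc)
    raise ValueError(f"unknown analytic excitation kind {kind!r}")


def center_expansion(kind: str, geometry: TrapGeometry,
                     trunc: SeriesTruncation = _DEFAULT_TRUNC) -> CenterExpansion:
    """Near-centre constants (gamma, alpha_coef) from the exact series.

    gamma is the centre value in units of the trapping voltage; alpha_coef is
    the quadratic coefficient in units of V_trap/a^2 with a the full cell
    dimension, evaluated by central second differences along z.
    """
    p = geometry.params
    if kind == "cubic":
        a = p["a"]
        v = p["v_trap"]
        f = lambda zz: cuboid_potential(0.0, 0.0, zz, a, a, a, v, trunc=trunc)
    elif kind == "cylindrical":
        a = 2 * p["R"]
        v = p["v_trap"]
        f = lambda zz: cylinder_potential(0.0, zz, p["R"], p["z0"], v, trunc=trunc)
    else:
        raise ValueError("center_expansion supports 'cubic' and 'cylindrical'")
    h = a / 400
    gamma = float(f(0.0)) / v
    d2 = (-float(f(2 * h)) + 16 * float(f(h)) - 30 * float(f(0.0))
          + 16 * float(f(-h)) - float(f(-2 * h))) / (12 * h**2)
    alpha_dim = 0.5 * d2  # coefficient of (z^2 - rho^2/2)
    return CenterExpansion(gamma=gamma, alpha_coef=alpha_dim * a**2 / v, a=a)
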