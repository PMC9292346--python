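"""Azimuthal averaging and least-squares extraction of harmonic coefficients.

The azimuthally averaged trapping potential is fitted, over the ion flight
region (rho, z <= 10 mm by default), with the axisymmetric even-harmonic
basis

    phi(rho, z) ~ C + A20 (z^2 - rho^2/2) + A40 (8z^4 - 24z^2 rho^2 + 3rho^4)
                  + A60 (16z^6 - 120z^4 rho^2 + 90z^2 rho^4 - 5rho^6),

by ordinary (unweighted) least squares on a uniform rectangular lattice.
Dimensionless coefficients are obtained by normalizing lengths with
d^2 = (1/2)(z0^2 + rho0^2/2): A20n = A20 d^2, A40n = A40 d^4, A60n = A60 d^6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .field_analytic import harmonic_basis
from .field_solver import PotentialGrid
from .trap_geometry import TrapGeometry

__all__ = ["AveragedPotential", "HarmonicFit", "azimuthal_average",
           "fit_harmonics", "calibrate_voltage"]

#: Fit-region half-extents (m) used for the comparative evaluation.
DEFAULT_FIT_REGION = (10e-3, 10e-3)

#: Fit lattice (n_rho, n_z) over [0, rho_max] x [-z_max, z_max].
DEFAULT_FIT_NODES = (41, 81)


@dataclass
class AveragedPotential:
    """Potential averaged over the polar angle, on a (rho, z) lattice."""

    rho_axis: np.ndarray
    z_axis: np.ndarray
    phi_bar: np.ndarray
    valid: np.ndarray  # False where the sampling circle touched an electrode

    def interpolator(self):
        return RegularGridInterpolator((self.rho_axis, self.z_axis), self.phi_bar)


@dataclass
class HarmonicFit:
    """Fitted harmonic coefficients, dimensional and dimensionless."""

    C: float
    A20: float          # V/m^2
    A40: float          # V/m^4
    A60: float          # V/m^6
    d: float            # m
    rms_residual: float  # V
    fit_region: tuple

    @property
    def A20n(self) -> float:
        return self.A20 * self.d**2

    @property
    def A40n(self) -> float:
        return self.A40 * self.d**4

    @property
    def A60n(self) -> float:
        return self.A60 * self.d**6

    def to_dict(self) -> dict:
        out = asdict(self)
        out.update(A20n=self.A20n, A40n=self.A40n, A60n=self.A60n)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def azimuthal_average(field: PotentialGrid, n_angles: int = 256) -> AveragedPotential:
    """Average a solved potential over the polar angle.

    For an axisymmetric solution this is the identity.  For 3-D grids the
    average is a trapezoidal quadrature over theta with trilinear
    interpolation; lattice nodes whose sampling circle intersects an
    electrode are flagged invalid and excluded from subsequent fits.
    """
    if not field.converged:
        raise ValueError("refusing to average a non-converged field")
    if field.axisymmetric:
        rho, zax = field.axes
        # interior nodes only: Dirichlet nodes are electrode territory
        valid = ~field.dirichlet_mask
        return AveragedPotential(rho, zax, field.phi.copy(), valid)
    if n_angles < 64:
        raise ValueError("n_angles >= 64 required")
    x, y, zax = field.axes
    rmax = min(x.max(), y.max())
    nr = int(np.ceil(rmax / min(field.spacing[:2]))) + 1
    rho = np.linspace(0.0, rmax, nr)
    interp = RegularGridInterpolator((x, y, zax), field.phi)
    mask_interp = RegularGridInterpolator((x, y, zax),
                                          field.dirichlet_mask.astype(float))
    ang = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    Rg, Zg, Tg = np.meshgrid(rho, zax, ang, indexing="ij")
    pts = np.column_stack([(Rg * np.cos(Tg)).ravel(),
                           (Rg * np.sin(Tg)).ravel(),
                           Zg.ravel()])
    phi = interp(pts).reshape(Rg.shape).mean(axis=2)
    touched = mask_interp(pts).reshape(Rg.shape).max(axis=2) > 0
    return AveragedPotential(rho, zax, phi, ~touched)


def fit_harmonics(avg: AveragedPotential, region=DEFAULT_FIT_REGION,
                  d: float = 1.0, nodes=DEFAULT_FIT_NODES) -> HarmonicFit:
    """Ordinary least-squares harmonic fit over rho <= region[0], |z| <= region[1].

    The averaged potential is sampled on a uniform lattice; nodes flagged
    invalid (electrode contact) are excluded.  Requires >= 100 usable nodes.
    """
    rho_max, z_max = region
    if rho_max > avg.rho_axis.max() + 1e-12 or z_max > avg.z_axis.max() + 1e-12:
        raise ValueError("fit region exceeds the averaged-potential grid")
    rr = np.linspace(0.0, rho_max, nodes[0])
    zz = np.linspace(-z_max, z_max, nodes[1])
    Rg, Zg = np.meshgrid(rr, zz, indexing="ij")
    interp = RegularGridInterpolator((avg.rho_axis, avg.z_axis), avg.phi_bar)
    vinterp = RegularGridInterpolator((avg.rho_axis, avg.z_axis),
                                      (~avg.valid).astype(float))
    pts = np.column_stack([Rg.ravel(), Zg.ravel()])
    phi = interp(pts).reshape(Rg.shape)
    ok = vinterp(pts).reshape(Rg.shape) == 0
    if ok.sum() < 100:
        raise ValueError("degenerate fit region: fewer than 100 usable nodes")
    # fit in region-scaled coordinates for conditioning, then rescale
    s = max(rho_max, z_max)
    b0, b2, b4, b6 = harmonic_basis(Rg / s, Zg / s)
    design = np.column_stack([b0[ok], b2[ok], b4[ok], b6[ok]])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("rank-deficient design matrix (degenerate region)")
    coef, *_ = np.linalg.lstsq(design, phi[ok], rcond=None)
    resid = phi[ok] - design @ coef
    return HarmonicFit(C=float(coef[0]), A20=float(coef[1] / s**2),
                       A40=float(coef[2] / s**4), A60=float(coef[3] / s**6), d=float(d),
                       rms_residual=float(np.sqrt(np.mean(resid**2))),
                       fit_region=(float(rho_max), float(z_max)))


def fit_lattice_potential(phi_fn, region=DEFAULT_FIT_REGION,
                          nodes=DEFAULT_FIT_NODES) -> AveragedPotential:
    """Evaluate an analytic averaged potential phi_fn(rho, z) on the fit lattice."""
    rr = np.linspace(0.0, region[0], nodes[0])
    zz = np.linspace(-region[1], region[1], nodes[1])
    Rg, Zg = np.meshgrid(rr, zz, indexing="ij")
    phi = phi_fn(Rg, Zg)
    return AveragedPotential(rr, zz, phi, np.ones_like(phi, bool))


def calibrate_voltage(trap: TrapGeometry, reference_A20: float,
                      fitted_A20: float | None = None) -> TrapGeometry:
    """Rescale all applied voltages so the dimensional A20 matches a reference.

    If ``fitted_A20`` is not supplied the trap is evaluated (analytic source
    when available, numeric otherwise) to obtain it.  By linearity of
    electrostatics the refitted A20 equals the reference exactly (up to
    solver tolerance).
    """
    if fitted_A20 is None:
        from .pipeline import harmonic_fit_for  # lazy: pipeline imports this module
        fitted_A20 = harmonic_fit_for(trap).A20
    if fitted_A20 == 0:
        raise ValueError("cannot calibrate a trap with zero fitted A20")
    return trap.with_voltage_scale(reference_A20 / fitted_A20)
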