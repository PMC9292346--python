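"""Ion eigenfrequencies, position-dependent reduced cyclotron frequency,
comet-formation time, and compensation-orthogonality analysis.

In a homogeneous field B along z an ion of mass m and charge q rotates at
the pure cyclotron frequency omega_c = qB/m.  A harmonic trapping term
A20 (z^2 - rho^2/2) splits the radial motion into the reduced-cyclotron
(omega_+) and magnetron (omega_-) branches,

    omega_± = omega_c/2 ± sqrt((omega_c/2)^2 - omega_z^2/2),
    omega_z = sqrt(2 q A20 / m),

with 2 omega_+ omega_- = omega_z^2 and
omega_c^2 = omega_+^2 + omega_-^2 + omega_z^2.

Higher even harmonics (A40, A60) make omega_+ depend on position; an ion
cloud occupying a range of (rho, z) then dephases into a "comet" once the
accumulated phase spread reaches 2 pi, after

    T_comet = 2 pi / (max omega_+ - min omega_+)

over the cloud region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as const
from .harmonic_analysis import HarmonicFit

__all__ = ["IonCloudSpec", "FrequencySet", "cyclotron_frequency",
           "eigenfrequencies", "local_reduced_frequency", "comet_time",
           "orthogonality_gamma", "find_orthogonal_ratio"]


@dataclass(frozen=True)
class IonCloudSpec:
    """Ion and cloud parameters of the comparative evaluation."""

    m_over_z: float = const.DEFAULT_M_OVER_Z  # Da per elementary charge
    charge_number: int = 1
    B: float = const.DEFAULT_B                # T
    r_cloud: float = const.DEFAULT_R_CLOUD    # m
    r_excitation: float = const.DEFAULT_R_EXCITATION  # m
    z_cloud: float = const.DEFAULT_Z_CLOUD    # m

    def __post_init__(self):
        if self.charge_number < 1:
            raise ValueError("charge_number must be >= 1")
        if self.r_excitation < self.r_cloud:
            raise ValueError("r_excitation must be >= r_cloud")

    @property
    def mass(self) -> float:
        """Ion mass (kg)."""
        return self.m_over_z * self.charge_number * const.ATOMIC_MASS_UNIT

    @property
    def charge(self) -> float:
        """Ion charge (C)."""
        return self.charge_number * const.ELEMENTARY_CHARGE


@dataclass(frozen=True)
class FrequencySet:
    """Angular eigenfrequencies (rad/s)."""

    omega_c: float
    omega_plus: float
    omega_minus: float
    omega_z: float


class StabilityError(ValueError):
    pass


def cyclotron_frequency(spec: IonCloudSpec) -> float:
    """Pure cyclotron frequency omega_c = qB/m (rad/s)."""
    if spec.m_over_z <= 0:
        raise ValueError("mass must be positive")
    return spec.charge * spec.B / spec.mass


def eigenfrequencies(A20: float, spec: IonCloudSpec) -> FrequencySet:
    """Eigenfrequencies for a harmonic trapping coefficient A20 (V/m^2)."""
    wc = cyclotron_frequency(spec)
    wz2 = 2 * spec.charge * A20 / spec.mass
    disc = (wc / 2) ** 2 - wz2 / 2
    if disc < 0:
        crit = spec.mass * wc**2 / (4 * spec.charge)
        raise StabilityError(
            f"unstable trapping: A20 = {A20:.6g} V/m^2 exceeds the critical "
            f"{crit:.6g} V/m^2 at this B and m/z")
    root = math.sqrt(disc)
    w_plus = wc / 2 + root
    # conjugate form avoids the cancellation in wc/2 - root for wz << wc
    w_minus = (wz2 / 2) / w_plus if w_plus > 0 else 0.0
    return FrequencySet(omega_c=wc, omega_plus=w_plus, omega_minus=w_minus,
                        omega_z=math.sqrt(max(wz2, 0.0)))


def _effective_a(fit: HarmonicFit, rho, z):
    """Local radial-field coefficient E_rho/rho (V/m^2) from the harmonic fit."""
    return (fit.A20
            + fit.A40 * (48 * z**2 - 12 * rho**2)
            + fit.A60 * (240 * z**4 - 360 * z**2 * rho**2 + 30 * rho**4))


def local_reduced_frequency(fit: HarmonicFit, rho, z, spec: IonCloudSpec):
    """Position-dependent reduced cyclotron frequency omega_+(rho, z) (rad/s)."""
    rho = np.asarray(rho, float)
    z = np.asarray(z, float)
    wc2 = cyclotron_frequency(spec) / 2
    disc = wc2**2 - spec.charge * _effective_a(fit, rho, z) / spec.mass
    if np.any(disc < 0):
        bad = np.argwhere(disc < 0)
        i = tuple(bad[0])
        raise StabilityError(
            f"locally unstable radial motion at rho={np.broadcast_to(rho, disc.shape)[i]:.4g} m, "
            f"z={np.broadcast_to(z, disc.shape)[i]:.4g} m")
    return wc2 + np.sqrt(disc)


def comet_time(fit: HarmonicFit, spec: IonCloudSpec | None = None,
               grid=(121, 161)) -> float:
    """Comet-formation (dephasing) time of the ion cloud (s).

    The extrema of omega_+ are searched on a dense rectangular grid over
    rho in [r_excitation - r_cloud, r_excitation + r_cloud],
    z in [-z_cloud, z_cloud].  Returns +inf when the frequency spread is
    below 1e-12 of omega_+ (no dephasing at this precision).
    """
    spec = spec or IonCloudSpec()
    rho = np.linspace(spec.r_excitation - spec.r_cloud,
                      spec.r_excitation + spec.r_cloud, grid[0])[:, None]
    z = np.linspace(-spec.z_cloud, spec.z_cloud, grid[1])[None, :]
    wp = local_reduced_frequency(fit, rho, z, spec)
    spread = float(wp.max() - wp.min())
    if spread < 1e-12 * float(wp.mean()):
        return math.inf
    return 2 * math.pi / spread


# ---------------------------------------------------------------------------
# orthogonalization (compensation-voltage decoupling)
# ---------------------------------------------------------------------------

_COMP_FAMILIES = ("hyperbolic_compensated", "cylindrical_compensated",
                  "open_compensated")

#: Near-centre fit region (m) for the quality factor: the gamma factor is
#: defined through the spherical-harmonic expansion about the trap centre,
#: so the fit must not alias the k >= 8 content of the outer working volume.
GAMMA_FIT_REGION = (5e-3, 5e-3)


def _basis_fit(family: str, ratio: float, spacing=None):
    """Harmonic fit of the unit-compensation-voltage basis solution."""
    from .field_solver import solve
    from .harmonic_analysis import fit_harmonics, azimuthal_average
    from .trap_geometry import make_trap, rasterize

    R0 = 0.0127
    if family == "hyperbolic_compensated":
        geom = make_trap(family, R=R0, ratio=ratio, v_trap=0.0, v_c=1.0)
    elif family == "cylindrical_compensated":
        geom = make_trap(family, R=ratio * R0, z0=R0, v_trap=0.0, v_c=1.0)
    else:
        geom = make_trap(family, R=ratio * R0, z0=R0, v_trap=0.0, v_c=1.0)
    grid = solve(rasterize(geom, spacing=spacing))
    avg = azimuthal_average(grid)
    return fit_harmonics(avg, region=GAMMA_FIT_REGION, d=geom.d), geom


def orthogonality_gamma(family: str, ratio: float, spacing=None) -> float:
    """Quality factor gamma = (V0 dA2/dVc) / (V0 dA4/dVc) at aspect ratio R/z0.

    Computed from a single unit-voltage basis solution of the compensation
    electrodes (the derivative in V_c is exact by superposition).  gamma = 0
    is the orthogonalized configuration: tuning V_c then changes A4 without
    shifting A2 (hence without shifting omega_+).
    """
    if family not in _COMP_FAMILIES:
        raise ValueError(f"family must be one of {_COMP_FAMILIES}")
    fit, geom = _basis_fit(family, ratio, spacing)
    dA2 = 2 * geom.d**2 * fit.A20          # Legendre-convention A_2 per volt of V_c
    dA4 = 16 * geom.d**4 * fit.A40
    if abs(dA4) < 1e-12 * max(abs(dA2), 1e-30):
        raise ZeroDivisionError("degenerate family: dA4/dVc vanishes at this ratio")
    return dA2 / dA4


def find_orthogonal_ratio(family: str, bracket=(0.8, 1.5), rtol: float = 1e-3,
                          spacing=None) -> float:
    """Aspect ratio R/z0 at which gamma crosses zero, by bisection."""
    lo, hi = sorted(bracket)
    glo = orthogonality_gamma(family, lo, spacing)
    ghi = orthogonality_gamma(family, hi, spacing)
    if glo * ghi > 0:
        raise ValueError(
            f"gamma does not change sign on [{lo}, {hi}]: gamma({lo})={glo:.3g}, "
            f"gamma({hi})={ghi:.3g}")
    while hi - lo > rtol * 0.5 * (hi + lo):
        mid = 0.5 * (lo + hi)
        g = orthogonality_gamma(family, mid, spacing)
        if g * glo > 0:
            lo, glo = mid, g
        else:
            hi = mid
    return 0.5 * (lo + hi)
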