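"""Image-charge detection: reciprocity weight fields, closed-form harmonic
content of cylindrical-cell signals, and multielectrode frequency multiplication.

By the reciprocity principle the charge induced on a detection electrode by
an ion of charge q at position r equals Q = -q phi_w(r), where phi_w is the
potential created with that electrode at 1 V and everything else grounded.
For a long cylindrical cell with a pair of wall sectors of half-angle alpha
the differential induced charge on a centred circular orbit of radius rho
contains only odd harmonics of the rotation frequency,

    Q_(2n+1)/q = 2 (rho/R)^(2n+1) sin((2n+1) alpha) / ((2n+1) pi),

so alpha = pi/3 (a 120-degree electrode) nulls the third harmonic.  Wiring
p alternating electrode pairs into two ensembles keeps only the orders
p(2n+1), multiplying the detected frequency (8 electrodes -> 4 omega_+).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .field_solver import PotentialGrid

__all__ = ["DetectionLayout", "HarmonicSpectrum", "reciprocity_charge",
           "cylinder_harmonics", "multielectrode_harmonics",
           "synthesize_transient"]


@dataclass(frozen=True)
class DetectionLayout:
    """Angular layout of the detection electrodes.

    ``half_angle`` is alpha (rad) of each electrode; ``n_pairs`` electrode
    pairs per ring (1 = dipolar); alternating wiring joins every other
    electrode into one of two ensembles.
    """

    half_angle: float
    n_pairs: int = 1
    alternating: bool = True

    def __post_init__(self):
        if not 0 < self.half_angle <= np.pi / (2 * self.n_pairs):
            raise ValueError(
                "half_angle must be in (0, pi/(2 n_pairs)] for non-overlapping electrodes")
        if self.n_pairs < 1:
            raise ValueError("n_pairs >= 1")


@dataclass
class HarmonicSpectrum:
    """Relative amplitudes (fraction of q) of the harmonic orders of omega_+."""

    orders: np.ndarray
    amplitudes: np.ndarray


def reciprocity_charge(weight_field: PotentialGrid, q: float, position) -> float:
    """Induced charge Q = -q phi_w at ``position`` (x, y, z).

    ``weight_field`` must be solved with the detection electrode(s) at 1 V and
    all other electrodes grounded.  For a differential (two-ensemble) signal,
    pass the difference of the two ensembles' weight fields or call twice.
    """
    pos = np.atleast_2d(np.asarray(position, float))
    if weight_field.axisymmetric:
        axes = weight_field.axes
        pts = np.column_stack([np.hypot(pos[:, 0], pos[:, 1]), pos[:, 2]])
    else:
        axes = weight_field.axes
        pts = pos
    interp = RegularGridInterpolator(axes, weight_field.phi, bounds_error=True)
    try:
        phi = interp(pts)
    except ValueError as exc:
        raise ValueError("position outside the weight-field grid") from exc
    out = -q * phi
    return float(out[0]) if np.asarray(position).ndim == 1 else out


def _sin_exact(x):
    """sin with structural nulls (integer multiples of pi) snapped to zero."""
    s = np.sin(x)
    return np.where(np.abs(s) < 1e-12, 0.0, s)


def cylinder_harmonics(rho_over_R: float, layout: DetectionLayout,
                       n_max: int = 10) -> HarmonicSpectrum:
    """Odd-harmonic content of the dipolar signal in a long cylindrical cell."""
    if layout.n_pairs != 1:
        raise ValueError("cylinder_harmonics is the dipolar (n_pairs = 1) form")
    if not 0 <= rho_over_R < 1:
        raise ValueError("rho/R must be in [0, 1)")
    n = np.arange(n_max)
    orders = 2 * n + 1
    amps = (rho_over_R ** orders * 2 * _sin_exact(orders * layout.half_angle)
            / (orders * np.pi))
    return HarmonicSpectrum(orders=orders, amplitudes=amps)


def multielectrode_harmonics(rho_over_R: float, layout: DetectionLayout,
                             n_max: int = 10) -> HarmonicSpectrum:
    """Surviving harmonics for p alternating pairs: orders p(2n+1).

    For p = 2 (four detection electrodes) the orders are 2, 6, 10, ... with
    amplitudes 4 (rho/R)^(4n+2) sin((4n+2) alpha)/((4n+2) pi); the general-p
    construction follows the same pattern with prefactor 2p.
    """
    if layout.n_pairs < 2:
        raise ValueError("multielectrode form needs n_pairs >= 2")
    if not layout.alternating:
        raise ValueError("multielectrode detection assumes alternating wiring")
    if not 0 <= rho_over_R < 1:
        raise ValueError("rho/R must be in [0, 1)")
    p = layout.n_pairs
    n = np.arange(n_max)
    orders = p * (2 * n + 1)
    amps = (rho_over_R ** orders * 2 * p * _sin_exact(orders * layout.half_angle)
            / (orders * np.pi))
    return HarmonicSpectrum(orders=orders, amplitudes=amps)


def synthesize_transient(spectrum: HarmonicSpectrum, omega_plus: float,
                         duration: float, sample_rate: float,
                         differentiate: bool = False):
    """Time-domain signal from a harmonic spectrum and its magnitude spectrum.

    The charge signal is sum_k a_k cos(k omega_+ t); with ``differentiate``
    the induced current dQ/dt is returned instead (each term scaled by its
    angular frequency).  Returns (t, signal, freqs, magnitude).
    """
    f_max = float(np.max(spectrum.orders)) * omega_plus / (2 * np.pi)
    if sample_rate <= 2 * f_max:
        raise ValueError(
            f"sample_rate {sample_rate:.4g} Hz violates Nyquist for the highest "
            f"harmonic at {f_max:.4g} Hz")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    sig = np.zeros(n)
    for k, a in zip(spectrum.orders, spectrum.amplitudes):
        if differentiate:
            sig -= a * k * omega_plus * np.sin(k * omega_plus * t)
        else:
            sig += a * np.cos(k * omega_plus * t)
    mag = np.abs(np.fft.rfft(sig)) / n * 2
    freqs = np.fft.rfftfreq(n, 1 / sample_rate)
    return t, sig, freqs, mag


def cylinder_weight_boundary(R: float, half_length: float, half_angle: float,
                             spacing: float):
    """Dirichlet problem for the weight field of one wall-sector electrode.

    The sector spans |theta| <= half_angle (centred on +x) along the full
    wall at 1 V; the rest of the wall and the end plates are grounded.
    Solve it with field_solver.solve (3-D) and feed the result to
    reciprocity_charge; by mirror symmetry the opposing electrode's weight
    field is phi_w(-x, y, z).
    """
    from .trap_geometry import BoundaryGrid
    nxy = 2 * max(int(round(R / spacing)), 8) + 1
    nz = 2 * max(int(round(half_length / spacing)), 8) + 1
    x = np.linspace(-R, R, nxy)
    zax = np.linspace(-half_length, half_length, nz)
    X, Y, Z = np.meshgrid(x, x, zax, indexing="ij")
    r = np.hypot(X, Y)
    th = np.arctan2(Y, X)
    # threshold at R - h/2 so the staircase wall is centred on the true
    # radius (a node-on-or-outside rule biases the effective radius by ~h/2,
    # which enters the m-th harmonic as a factor (R_eff/R)^m)
    mask = r >= R - spacing / 2
    # antialias the sector edge: wall nodes subtend ~spacing/R of arc, so a
    # binary assignment misplaces the edge by O(h); a linear ramp over one
    # node width restores O(h^2) accuracy of the low-order harmonics
    ramp = spacing / R
    frac = np.clip((half_angle - np.abs(th)) / ramp + 0.5, 0.0, 1.0)
    val = np.where(mask, frac, 0.0)
    mask = mask.copy()
    mask[:, :, 0] = True
    mask[:, :, -1] = True
    val[:, :, 0] = 0.0
    val[:, :, -1] = 0.0
    return BoundaryGrid(axes=(x, x, zax), dirichlet_mask=mask,
                        dirichlet_value=val, axisymmetric=False)
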