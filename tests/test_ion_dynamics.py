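"""Eigenfrequencies, comet-formation time, orthogonality scans."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icrcell import (IonCloudSpec, comet_time, cyclotron_frequency,
                     eigenfrequencies, find_orthogonal_ratio,
                     local_reduced_frequency, orthogonality_gamma)
from icrcell.harmonic_analysis import HarmonicFit
from icrcell.ion_dynamics import StabilityError


def _fit(C=0.0, A20=4000.0, A40=0.0, A60=0.0, d=0.011):
    return HarmonicFit(C=C, A20=A20, A40=A40, A60=A60, d=d,
                       rms_residual=0.0, fit_region=(1e-2, 1e-2))


def test_cyclotron_frequency_reference_ion():
    """m/z 500 at 7 T rotates at ~1.351e6 rad/s (215 kHz)."""
    assert cyclotron_frequency(IonCloudSpec()) == pytest.approx(1.351e6, rel=1e-3)


def test_cyclotron_frequency_scalings():
    spec = IonCloudSpec()
    assert cyclotron_frequency(IonCloudSpec(B=0.0)) == 0.0
    assert cyclotron_frequency(IonCloudSpec(B=14.0)) == pytest.approx(
        2 * cyclotron_frequency(spec), rel=1e-14)
    assert cyclotron_frequency(IonCloudSpec(m_over_z=250.0)) == pytest.approx(
        2 * cyclotron_frequency(spec), rel=1e-14)


def test_zero_field_limits():
    spec = IonCloudSpec()
    f = eigenfrequencies(0.0, spec)
    assert f.omega_plus == f.omega_c
    assert f.omega_minus == 0.0 and f.omega_z == 0.0


@settings(derandomize=True, max_examples=100)
@given(st.floats(min_value=1e-6, max_value=0.99))
def test_frequency_identities_hold(frac):
    """2 w+ w- = wz^2 and wc^2 = w+^2 + w-^2 + wz^2 to 1e-12 relative."""
    spec = IonCloudSpec()
    crit = spec.mass * cyclotron_frequency(spec) ** 2 / (4 * spec.charge)
    f = eigenfrequencies(frac * crit, spec)
    assert 2 * f.omega_plus * f.omega_minus == pytest.approx(f.omega_z**2, rel=1e-12)
    assert f.omega_c**2 == pytest.approx(
        f.omega_plus**2 + f.omega_minus**2 + f.omega_z**2, rel=1e-12)


def test_instability_names_critical_a20():
    spec = IonCloudSpec()
    crit = spec.mass * cyclotron_frequency(spec) ** 2 / (4 * spec.charge)
    with pytest.raises(StabilityError, match="critical"):
        eigenfrequencies(1.01 * crit, spec)


def test_magnetron_scales_inversely_with_field():
    """In the small-wz/wc limit, doubling B halves the magnetron frequency."""
    s1 = IonCloudSpec(B=7.0)
    s2 = IonCloudSpec(B=14.0)
    a20 = 4000.0
    r = eigenfrequencies(a20, s1).omega_minus / eigenfrequencies(a20, s2).omega_minus
    assert r == pytest.approx(2.0, rel=1e-3)


def test_local_frequency_reduces_to_eigenfrequency():
    spec = IonCloudSpec()
    fit = _fit(A20=4000.0)
    wp = local_reduced_frequency(fit, np.linspace(0, 8e-3, 5),
                                 np.linspace(-8e-3, 8e-3, 5), spec)
    assert np.ptp(wp) == 0.0
    assert wp.flat[0] == pytest.approx(eigenfrequencies(4000.0, spec).omega_plus,
                                       rel=1e-14)


def test_positive_a40_lowers_frequency_with_axial_amplitude():
    """A40 > 0 strengthens the radial field as z^2 grows, pulling omega_+ down."""
    spec = IonCloudSpec()
    fit = _fit(A20=4000.0, A40=1e6)
    z = np.linspace(0, 8e-3, 9)
    wp = local_reduced_frequency(fit, 6e-3, z, spec)
    assert (np.diff(wp) < 0).all()


def test_local_instability_reports_position():
    spec = IonCloudSpec()
    fit = _fit(A20=4000.0, A40=1e12)
    with pytest.raises(StabilityError, match="z="):
        local_reduced_frequency(fit, 6e-3, 8e-3, spec)


def test_comet_time_is_two_pi_over_spread():
    spec = IonCloudSpec()
    fit = _fit(A20=4000.0, A40=3e5, A60=-1e9)
    rho = np.linspace(spec.r_excitation - spec.r_cloud,
                      spec.r_excitation + spec.r_cloud, 121)[:, None]
    z = np.linspace(-spec.z_cloud, spec.z_cloud, 161)[None, :]
    wp = local_reduced_frequency(fit, rho, z, spec)
    assert comet_time(fit, spec) == pytest.approx(
        2 * math.pi / (wp.max() - wp.min()), rel=1e-14)


def test_comet_time_ideal_field_is_infinite():
    assert comet_time(_fit(A20=4000.0)) == math.inf


def test_comet_time_invariant_under_constant_offset():
    t1 = comet_time(_fit(C=0.0, A20=4000.0, A40=3e5))
    t2 = comet_time(_fit(C=17.0, A20=4000.0, A40=3e5))
    assert t1 == t2


def test_comet_time_halves_when_spread_doubles():
    """Doubling the anharmonic coefficients doubles the frequency spread
    (to first order) and halves the dephasing time."""
    t1 = comet_time(_fit(A20=4000.0, A40=3e5, A60=-1e9))
    t2 = comet_time(_fit(A20=4000.0, A40=6e5, A60=-2e9))
    assert t1 / t2 == pytest.approx(2.0, rel=1e-3)


def test_cloud_spec_validation():
    with pytest.raises(ValueError):
        IonCloudSpec(r_cloud=7e-3, r_excitation=6e-3)
    with pytest.raises(ValueError):
        IonCloudSpec(charge_number=0)


def test_gamma_scan_brackets_a_root():
    """gamma changes sign across the orthogonal aspect ratio and the
    bisection finds the same root from either bracket orientation."""
    lo = orthogonality_gamma("hyperbolic_compensated", 1.05, spacing=2e-4)
    hi = orthogonality_gamma("hyperbolic_compensated", 1.30, spacing=2e-4)
    assert lo * hi < 0
    r1 = find_orthogonal_ratio("hyperbolic_compensated", (1.05, 1.30),
                               rtol=5e-3, spacing=2e-4)
    r2 = find_orthogonal_ratio("hyperbolic_compensated", (1.30, 1.05),
                               rtol=5e-3, spacing=2e-4)
    assert r1 == pytest.approx(r2, rel=5e-3)
    with pytest.raises(ValueError, match="change sign"):
        find_orthogonal_ratio("hyperbolic_compensated", (0.85, 0.95),
                              rtol=5e-3, spacing=2e-4)


def test_compensation_suppresses_a40(all_rows):
    """At the published compensation voltage the closed compensated cylinder's
    |A40n| drops far below the uncompensated cylindrical cell's 1e-2."""
    plain = all_rows["cylindrical"]
    comp = all_rows["cylindrical_compensated"]
    assert abs(comp.A40n) < abs(plain.A40n) / 20


def test_open_compensated_a40_null_also_suppresses_a60():
    """The V_c that nulls A40 in the open compensated cell leaves |A60n|
    below 1e-3 as well (the design's selling point)."""
    from icrcell.field_solver import solve
    from icrcell.harmonic_analysis import azimuthal_average, fit_harmonics
    from icrcell.trap_geometry import make_trap, rasterize

    h = 1.5e-4
    base = make_trap("open_compensated", v_c=0.0)
    comp = make_trap("open_compensated", v_trap=0.0, v_c=1.0)
    f0 = fit_harmonics(azimuthal_average(solve(rasterize(base, spacing=h))), d=base.d)
    fc = fit_harmonics(azimuthal_average(solve(rasterize(comp, spacing=h))), d=comp.d)
    vc_null = -f0.A40 / fc.A40
    a60n = (f0.A60 + vc_null * fc.A60) * base.d**6
    assert abs(a60n) < 1e-3
    # and the null voltage is in the neighbourhood of the published 0.3235 V
    assert vc_null == pytest.approx(0.3235, rel=0.25)
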