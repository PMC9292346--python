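"""Closed-form/series potentials: reference constants, symmetries, Laplace."""

import numpy as np
import pytest

from icrcell import (IdealFieldParams, SeriesTruncation, center_expansion,
                     compensated_sensitivity, excitation_potential, make_trap,
                     paracell_average_consistency, trapping_potential)
from icrcell.field_analytic import (cubic_dipolar_potential, cuboid_averaged,
                                    cuboid_potential,
                                    cylinder_dipolar_potential,
                                    cylinder_potential, ideal_potential,
                                    paracell_averaged_potential,
                                    paracell_full_potential)


def test_cylinder_center_potential_reference_value():
    """Aspect-ratio-one closed cylinder: centre potential / V_trap = 0.2787."""
    v = cylinder_potential(0.0, 0.0, 0.0127, 0.0127, 1.0)
    assert v == pytest.approx(0.2787, abs=1e-3)


def test_center_expansion_cylindrical_constants():
    ce = center_expansion("cylindrical", make_trap("cylindrical"))
    assert ce.gamma == pytest.approx(0.2787, rel=5e-4)
    assert ce.alpha_coef == pytest.approx(2.8404, rel=5e-4)
    assert ce.a == 2 * 0.0127


def test_center_expansion_cubic_constants():
    """Cubic cell: centre value is exactly 1/3 of the trapping voltage."""
    ce = center_expansion("cubic", make_trap("cubic"))
    assert ce.gamma == pytest.approx(1.0 / 3.0, abs=1e-9)
    assert ce.alpha_coef == pytest.approx(2.7737, rel=1e-3)


def test_center_expansion_matches_quadratic_fit():
    """gamma/alpha agree with a least-squares quadratic in a ball of radius a/20."""
    geom = make_trap("cylindrical")
    ce = center_expansion("cylindrical", geom)
    p = geom.params
    rng = np.random.default_rng(7)
    n = 500
    r = p["R"] / 10 * rng.random(n) ** (1 / 3)
    costh = rng.uniform(-1, 1, n)
    z = r * costh
    rho = r * np.sqrt(1 - costh**2)
    v = cylinder_potential(rho, z, p["R"], p["z0"], 1.0)
    design = np.column_stack([np.ones(n), z**2 - rho**2 / 2])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    assert coef[0] == pytest.approx(ce.gamma, rel=1e-4)
    assert coef[1] * ce.a**2 == pytest.approx(ce.alpha_coef, rel=1e-3)


@pytest.mark.parametrize("name,fn", [
    ("ideal", lambda r, z: ideal_potential(r, z, IdealFieldParams(1234.0, 0.1))),
    ("cylinder", lambda r, z: cylinder_potential(r, z, 0.0127, 0.0127, 1.0)),
    ("paracell_avg", lambda r, z: paracell_averaged_potential(
        r, z, 0.0127, 0.0254, 0.9, 3.06)),
])
def test_axisymmetric_potentials_satisfy_laplace(name, fn):
    """Discrete axisymmetric Laplacian vanishes to O(h^2) at interior points."""
    h = 1e-4
    rho = np.linspace(h, 6e-3, 12)[:, None]
    z = np.linspace(-6e-3, 6e-3, 13)[None, :]
    lap = ((fn(rho + h, z) - 2 * fn(rho, z) + fn(rho - h, z)) / h**2
           + (fn(rho + h, z) - fn(rho - h, z)) / (2 * rho * h)
           + (fn(rho, z + h) - 2 * fn(rho, z) + fn(rho, z - h)) / h**2)
    scale = np.abs(fn(rho, z)).max() / (6e-3) ** 2
    assert np.abs(lap).max() < 1e-3 * scale


def test_cuboid_potential_satisfies_laplace_3d():
    a = 0.0254
    h = a / 400
    pts = np.linspace(-4e-3, 4e-3, 5)
    X, Y, Z = np.meshgrid(pts, pts, pts, indexing="ij")
    f = lambda x, y, z: cuboid_potential(x, y, z, a, a, a, 1.0)
    lap = sum(
        (f(X + dx * h, Y + dy * h, Z + dz * h) - 2 * f(X, Y, Z)
         + f(X - dx * h, Y - dy * h, Z - dz * h)) / h**2
        for dx, dy, dz in [(1, 0, 0), (0, 1, 0), (0, 0, 1)])
    assert np.abs(lap).max() < 1e-3 / (4e-3) ** 2


def test_cuboid_boundary_value_at_trapping_plate():
    """The series approaches the plate voltage linearly in the gap distance
    (Dirichlet limit at the plate centre)."""
    a = 0.0254
    trunc = SeriesTruncation(max_terms=800, tol=1e-8)
    gaps = np.array([0.02, 0.01, 0.005])
    dev = np.array([1.0 - cuboid_potential(0.0, 0.0, (0.5 - g) * a, a, a, a, 1.0,
                                           trunc=trunc) for g in gaps])
    assert dev[-1] == pytest.approx(0.0, abs=2.5e-2)
    np.testing.assert_allclose(dev / gaps, dev[0] / gaps[0], rtol=2e-3)


def test_cuboid_averaged_matches_quadrature():
    """The J0-weighted average equals a direct theta quadrature of the box series."""
    a = 0.0254
    rho, z = 6e-3, 4e-3
    th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    direct = cuboid_potential(rho * np.cos(th), rho * np.sin(th),
                              np.full_like(th, z), a, a, a, 1.0).mean()
    assert cuboid_averaged(rho, z, a, a, a, 1.0) == pytest.approx(direct, rel=1e-9)


def test_voltage_linearity():
    a = 0.0254
    p1 = cuboid_potential(2e-3, 1e-3, 3e-3, a, a, a, 1.0)
    p3 = cuboid_potential(2e-3, 1e-3, 3e-3, a, a, a, 3.0)
    assert p3 == pytest.approx(3 * p1, rel=1e-12)
    c1 = cylinder_potential(2e-3, 3e-3, 0.0127, 0.0127, 0.988)
    c2 = cylinder_potential(2e-3, 3e-3, 0.0127, 0.0127, 2 * 0.988)
    assert c2 == pytest.approx(2 * c1, rel=1e-12)


def test_trapping_potentials_even_in_z():
    a = 0.0254
    assert cuboid_potential(2e-3, 1e-3, 3e-3, a, a, a, 1.0) == pytest.approx(
        cuboid_potential(2e-3, 1e-3, -3e-3, a, a, a, 1.0), rel=1e-12)
    assert cylinder_potential(2e-3, 3e-3, 0.0127, 0.0127, 1.0) == pytest.approx(
        cylinder_potential(2e-3, -3e-3, 0.0127, 0.0127, 1.0), rel=1e-12)


def test_dipolar_potentials_odd_in_x():
    geom = make_trap("cubic")
    pt = np.array([3e-3, 2e-3, 4e-3])
    mpt = pt * np.array([-1, 1, 1])
    v = excitation_potential("cubic_dipolar", geom, pt)
    assert excitation_potential("cubic_dipolar", geom, mpt) == pytest.approx(-v, rel=1e-12)
    assert excitation_potential("cubic_dipolar", geom, np.array([0.0, 2e-3, 4e-3])) == 0.0
    cyl = make_trap("cylindrical")
    v = excitation_potential("cylindrical_dipolar", cyl, pt)
    assert excitation_potential("cylindrical_dipolar", cyl, mpt) == pytest.approx(-v, rel=1e-10)


def test_cubic_dipolar_near_center_coefficient():
    """Linear coefficient beta_1 = 0.721 (in units of V_dipolar/a)."""
    a = 0.0254
    h = a / 200
    beta1 = (cubic_dipolar_potential(h, 0, 0, a, 1.0)
             - cubic_dipolar_potential(-h, 0, 0, a, 1.0)) / (2 * h) * a
    assert beta1 == pytest.approx(0.721, abs=1e-3)


def test_cylindrical_dipolar_z_dependence_vanishes_for_long_cells():
    """The axial modulation of the excitation field disappears as z0/R grows,
    approaching the z-free infinite-cylinder form."""
    R = 0.0127
    z = np.linspace(-0.5 * R, 0.5 * R, 11)
    spans = {}
    for aspect in (1.0, 8.0):
        v = cylinder_dipolar_potential(np.full_like(z, 0.5 * R), np.zeros_like(z),
                                       z, R, aspect * R, 1.0)
        spans[aspect] = np.ptp(v)
    assert spans[8.0] < 1e-3 * spans[1.0]
    # long-cell mid-plane value matches the 2-D sector series
    m = np.arange(1, 400, 2)
    v2d = np.sum(4 * np.sin(m * np.pi / 4) / (m * np.pi) * 0.5**m)
    vlong = cylinder_dipolar_potential(0.5 * R, 0.0, 0.0, R, 8 * R, 1.0)
    assert vlong == pytest.approx(v2d, rel=1e-6)


def test_point_outside_cell_rejected():
    with pytest.raises(ValueError, match="outside"):
        trapping_potential("cylindrical", make_trap("cylindrical"),
                           np.array([0.02, 0.0, 0.0]))
    with pytest.raises(ValueError, match="outside"):
        trapping_potential("cubic", make_trap("cubic"), np.array([0.0, 0.0, 0.02]))


def test_paracell_average_consistency_is_exact():
    """The theta average of the full leaf-pattern potential reproduces the
    closed-form averaged potential (mean-value property of the per-slice
    harmonic extension)."""
    geom = make_trap("paracell")
    report = paracell_average_consistency(geom, n_theta=512)
    assert report["max"] < 1e-10 * geom.v_trap
    assert report["on_axis_max"] < 1e-10 * geom.v_trap


def test_paracell_full_boundary_values():
    """Near the wall the full potential approaches phi0 on a biased sector
    and 0 on a leaf centre; on the axis it stays between."""
    p = make_trap("paracell").params
    R, z0, N, beta, phi0 = p["R"], p["z0"], p["N"], p["beta"], p["v_trap"]
    mid_sector = np.pi / N  # centre of a biased sector
    v_biased = paracell_full_potential(0.999 * R, mid_sector, 0.0, R, z0, N, beta, phi0)
    v_leaf = paracell_full_potential(0.999 * R, 0.0, 0.0, R, z0, N, beta, phi0)
    assert v_biased == pytest.approx(phi0, rel=2e-2)
    assert abs(v_leaf) < 5e-2 * phi0
    v_axis = paracell_full_potential(0.0, 0.0, 0.0, R, z0, N, beta, phi0)
    assert 0 < v_axis < phi0


def test_compensated_sensitivity_limits_and_errors():
    R, z0 = 1.16 * 0.0127, 0.0127
    tiny = compensated_sensitivity(R, z0, 1e-6 * z0, 4)
    assert abs(tiny) < 1e-8
    with pytest.raises(ValueError):
        compensated_sensitivity(R, z0, 0.3 * z0, 3)
    with pytest.raises(ValueError):
        compensated_sensitivity(R, z0, 2.5 * z0, 4)


def test_compensated_sensitivity_matches_solver_oracle():
    """The eigenfunction-expansion sensitivity agrees with a finite-difference
    oracle (unit-V_c basis solve of the compensated cylinder, local fit)."""
    from icrcell.field_solver import solve
    from icrcell.harmonic_analysis import azimuthal_average, fit_harmonics
    from icrcell.trap_geometry import rasterize

    R, z0, dz = 1.16 * 0.0127, 0.0127, 0.3 * 0.0127
    geom = make_trap("cylindrical_compensated", R=R, z0=z0, dz_c=dz,
                     v_trap=0.0, v_c=1.0)
    grid = solve(rasterize(geom))
    fit = fit_harmonics(azimuthal_average(grid), region=(5e-3, 5e-3), d=geom.d)
    oracle_k4 = 16 * geom.d**4 * fit.A40
    assert compensated_sensitivity(R, z0, dz, 4) == pytest.approx(oracle_k4, rel=0.05)


def test_series_truncation_validation():
    with pytest.raises(ValueError):
        SeriesTruncation(max_terms=0)
    with pytest.raises(ValueError):
        SeriesTruncation(tol=-1.0)
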