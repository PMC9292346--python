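"""Parametric construction of historical ICR (Penning) measuring-cell geometries.

Each cell design is built as a list of labelled electrodes, where an electrode
is an implicit solid region (a vectorized point-membership predicate in cell
coordinates) together with a role and an applied DC voltage.  The same
geometry object drives both the analytic field routines and the rasterizer
that prepares Dirichlet boundary grids for the numeric Laplace solver.

Conventions: z is along the magnetic field, the origin is the trap centre,
SI units throughout.  All designs in scope have reflection symmetry across
z = 0.  For the trapping-field computation the excitation/detection
electrodes of closed cells are held at 0 V.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TRAP_KINDS",
    "ROLES",
    "ElectrodeSpec",
    "TrapGeometry",
    "BoundaryGrid",
    "make_trap",
    "rasterize",
    "paracell_averaged_boundary",
    "paracell_leaf_halfwidth",
]

ROLES = ("trapping", "excitation", "detection", "compensation", "ground")

#: Inch in metres; several historical designs are specified in inches.
INCH = 0.0254

Region = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ElectrodeSpec:
    """One electrode: a solid implicit region with a role and a DC voltage."""

    label: str
    role: str
    voltage: float
    region: Region

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role {self.role!r} not in {ROLES}")
        if not math.isfinite(self.voltage):
            raise ValueError("electrode voltage must be finite")


@dataclass(frozen=True)
class TrapGeometry:
    """A cell design: electrodes plus characteristic lengths.

    ``R`` and ``z0`` are the radial and axial characteristic distances used
    for the normalization length d, with d^2 = (1/2)(z0^2 + (1/2) rho0^2);
    ``rho0`` defaults to R.  ``box`` is the half-extent of the simulation
    domain: (rho_max, z_max) for axisymmetric designs, (x, y, z) half-extents
    otherwise.
    """

    kind: str
    electrodes: tuple[ElectrodeSpec, ...]
    R: float
    z0: float
    rho0: float
    symmetry: str
    axisymmetric: bool
    box: tuple[float, ...]
    params: dict = field(default_factory=dict)
    voltage_params: tuple[str, ...] = ()

    @property
    def d(self) -> float:
        """Normalization length d, d^2 = (1/2)(z0^2 + rho0^2/2)."""
        return math.sqrt(0.5 * (self.z0**2 + 0.5 * self.rho0**2))

    @property
    def v_trap(self) -> float:
        volts = [e.voltage for e in self.electrodes if e.role == "trapping"]
        return max(volts, key=abs) if volts else 0.0

    def with_voltage_scale(self, factor: float) -> "TrapGeometry":
        """Scale every applied (non-ground) voltage by ``factor``."""
        new_params = dict(self.params)
        for name in self.voltage_params:
            new_params[name] = new_params[name] * factor
        return make_trap(self.kind, **new_params)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "params": dict(self.params),
            "electrodes": [
                {"label": e.label, "role": e.role, "voltage": e.voltage}
                for e in self.electrodes
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def from_dict(doc: dict) -> "TrapGeometry":
        return make_trap(doc["kind"], **doc.get("params", {}))

    @staticmethod
    def from_json(path) -> "TrapGeometry":
        with open(path) as fh:
            return TrapGeometry.from_dict(json.load(fh))


@dataclass
class BoundaryGrid:
    """Rasterized Dirichlet data on a uniform grid.

    ``axes`` is (rho, z) for axisymmetric grids or (x, y, z) otherwise;
    ``dirichlet_mask`` flags electrode (and closure) nodes and
    ``dirichlet_value`` holds their voltages.
    """

    axes: tuple[np.ndarray, ...]
    dirichlet_mask: np.ndarray
    dirichlet_value: np.ndarray
    axisymmetric: bool

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(float(a[1] - a[0]) for a in self.axes)


def _rho(x, y):
    return np.hypot(x, y)


# ---------------------------------------------------------------------------
# builders, one per design; defaults are the reference (Table-style) values
# ---------------------------------------------------------------------------


def _hyperbolic(compensated: bool, **p):
    R = p.setdefault("R", 0.0127)
    ratio = p.setdefault("ratio", 1.16)  # R/z0
    v_trap = p.setdefault("v_trap", 0.87)
    rho_max = p.setdefault("rho_max", 2 * R)
    z0 = R / ratio
    electrodes = [
        ElectrodeSpec(
            "endcaps", "trapping", v_trap,
            lambda x, y, z, R=R, z0=z0, rm=rho_max: (
                (2 * z**2 - (_rho(x, y))**2 >= 2 * z0**2) & (_rho(x, y) <= rm)
            ),
        ),
        ElectrodeSpec(
            # the ring is split into excitation/detection pairs in practice;
            # for the trapping field it is one 0 V surface
            "ring", "excitation", 0.0,
            lambda x, y, z, R=R, z0=z0, rm=rho_max: (
                ((_rho(x, y))**2 - 2 * z**2 >= R**2) & (_rho(x, y) <= rm)
            ),
        ),
    ]
    voltage_params = ["v_trap"]
    if compensated:
        v_c = p.setdefault("v_c", 0.455)
        r_c = p.setdefault("r_c", 2 * R)
        shell = (r_c, 1.1 * r_c)

        def theta_endcap(r):
            return math.acos(math.sqrt((2 * z0**2 + r**2) / (3 * r**2)))

        def theta_ring(r):
            return math.acos(math.sqrt((1 - R**2 / r**2) / 3))

        t_lo = max(theta_endcap(shell[0]), theta_endcap(shell[1]))
        t_hi = min(theta_ring(shell[0]), theta_ring(shell[1]))
        dt = t_hi - t_lo
        if dt <= 0:
            raise ValueError("no angular gap for the compensation electrode")
        electrodes.append(
            ElectrodeSpec(
                "compensation_arcs", "compensation", v_c,
                lambda x, y, z, s=shell, lo=t_lo + 0.1 * dt, hi=t_hi - 0.1 * dt: (
                    (lambda r, th: (r >= s[0]) & (r <= s[1]) & (th > lo) & (th < hi))(
                        np.hypot(_rho(x, y), z),
                        np.arctan2(_rho(x, y), np.abs(z)),
                    )
                ),
            )
        )
        voltage_params.append("v_c")
    return dict(
        electrodes=electrodes, R=R, z0=z0, rho0=R,
        symmetry="axisymmetric", axisymmetric=True,
        box=(2.8 * R, 2.2 * R), voltage_params=tuple(voltage_params), params=p,
    )


def _cuboid(**p):
    # trapping plates normal to z, long axis along x
    a = p.setdefault("a", 3 * INCH)
    b = p.setdefault("b", INCH)
    c = p.setdefault("c", INCH)
    v_trap = p.setdefault("v_trap", 1.2)
    electrodes = [
        ElectrodeSpec("trapping_plates", "trapping", v_trap,
                      lambda x, y, z, c=c: np.abs(z) >= c / 2),
        ElectrodeSpec("excitation_plates", "excitation", 0.0,
                      lambda x, y, z, a=a, c=c: (np.abs(x) >= a / 2) & (np.abs(z) < c / 2)),
        ElectrodeSpec("detection_plates", "detection", 0.0,
                      lambda x, y, z, a=a, b=b, c=c: (
                          (np.abs(y) >= b / 2) & (np.abs(x) < a / 2) & (np.abs(z) < c / 2))),
    ]
    return dict(
        electrodes=electrodes, R=min(a, b) / 2, z0=c / 2, rho0=max(a, b) / 2,
        symmetry="mirror_xy_only", axisymmetric=False,
        box=(a / 2, b / 2, c / 2), voltage_params=("v_trap",), params=p,
    )


def _cubic(**p):
    a = p.setdefault("a", INCH)
    v_trap = p.setdefault("v_trap", 1.0)
    out = _cuboid(a=a, b=a, c=a, v_trap=v_trap)
    out["symmetry"] = "N_fold:4"
    out["rho0"] = a / 2
    out["params"] = p
    return out


def _cyl_wall_stack(R, sections, z_box):
    """Wall electrodes (rho >= R) split into z-sections [(z_lo, z_hi, label, role, V)]."""
    out = []
    for z_lo, z_hi, label, role, volt in sections:
        out.append(
            ElectrodeSpec(
                label, role, volt,
                lambda x, y, z, R=R, a=z_lo, b=z_hi: (
                    (_rho(x, y) >= R) & (np.abs(z) >= a) & (np.abs(z) < b)),
            )
        )
    return out


def _cylindrical(**p):
    R = p.setdefault("R", 0.0127)
    z0 = p.setdefault("z0", 0.0127)
    v_trap = p.setdefault("v_trap", 0.988)
    electrodes = [
        ElectrodeSpec("endcaps", "trapping", v_trap,
                      lambda x, y, z, z0=z0: np.abs(z) >= z0),
        *_cyl_wall_stack(R, [(0.0, z0, "wall", "excitation", 0.0)], z0),
    ]
    return dict(
        electrodes=electrodes, R=R, z0=z0, rho0=R,
        symmetry="axisymmetric", axisymmetric=True,
        box=(R, z0), voltage_params=("v_trap",), params=p,
    )


def _cylindrical_compensated(**p):
    R = p.setdefault("R", 1.16 * 0.0127)
    z0 = p.setdefault("z0", 0.0127)
    dz_c = p.setdefault("dz_c", 0.3 * 0.0127)
    v_trap = p.setdefault("v_trap", 1.0)
    v_c = p.setdefault("v_c", 0.145)
    electrodes = [
        ElectrodeSpec("endcaps", "trapping", v_trap,
                      lambda x, y, z, z0=z0: np.abs(z) >= z0),
        *_cyl_wall_stack(R, [
            (0.0, z0 - dz_c, "wall", "excitation", 0.0),
            (z0 - dz_c, z0, "compensation_rings", "compensation", v_c),
        ], z0),
    ]
    return dict(
        electrodes=electrodes, R=R, z0=z0, rho0=R,
        symmetry="axisymmetric", axisymmetric=True,
        box=(R, z0), voltage_params=("v_trap", "v_c"), params=p,
    )


def _open_compensated(**p):
    z0 = p.setdefault("z0", 0.0127)
    R = p.setdefault("R", 1.0239 * 0.0127)
    dz_c = p.setdefault("dz_c", 0.8351 * 0.0127)
    z_e = p.setdefault("z_e", 4.327 * 0.0127)
    v_trap = p.setdefault("v_trap", 1.949)
    v_c = p.setdefault("v_c", 0.3235)
    electrodes = _cyl_wall_stack(R, [
        (0.0, z0 - dz_c, "central", "excitation", 0.0),
        (z0 - dz_c, z0, "compensation_rings", "compensation", v_c),
        (z0, z0 + z_e, "trapping_cylinders", "trapping", v_trap),
    ], z0 + z_e)
    return dict(
        electrodes=electrodes, R=R, z0=z0, rho0=R,
        symmetry="axisymmetric", axisymmetric=True,
        box=(R, z0 + z_e), voltage_params=("v_trap", "v_c"), params=p,
    )


def _tolmachev(**p):
    R = p.setdefault("R", 0.0127)
    z0 = p.setdefault("z0", 1.3 * 0.0127)
    dz1 = p.setdefault("dz1", 0.4 * 0.0127)
    dz2 = p.setdefault("dz2", 0.4 * 0.0127)
    z_e = p.setdefault("z_e", 2 * 0.0127)
    v_trap = p.setdefault("v_trap", 2.3)
    v_c1 = p.setdefault("v_c1", 0.1333 * 2.3)
    v_c2 = p.setdefault("v_c2", 0.3167 * 2.3)
    electrodes = _cyl_wall_stack(R, [
        (0.0, z0 - dz1 - dz2, "central", "excitation", 0.0),
        (z0 - dz1 - dz2, z0 - dz2, "compensation_inner", "compensation", v_c1),
        (z0 - dz2, z0, "compensation_outer", "compensation", v_c2),
        (z0, z0 + z_e, "trapping_cylinders", "trapping", v_trap),
    ], z0 + z_e)
    return dict(
        electrodes=electrodes, R=R, z0=z0, rho0=R,
        symmetry="axisymmetric", axisymmetric=True,
        box=(R, z0 + z_e), voltage_params=("v_trap", "v_c1", "v_c2"), params=p,
    )


def _brustkern(**p):
    R = p.setdefault("R", 0.0127)
    a = p.setdefault("a", 0.0127 / 31.24)
    k = p.setdefault("k", 0.06269)
    # electrode stack from the centre; the trapping-ring length and the grounded
    # outer cylinder are only loosely constrained by the published description
    z1 = 12.22 * a
    z2 = z1 + 1.55 * a
    z3 = z2 + 5.05 * a
    z4 = z3 + 3.05 * a          # = 21.87 a, inner edge of the trapping ring
    z5 = 2 * z4                 # trapping ring of length 21.87 a
    z6 = z5 + 1.5 * z5          # grounded outer cylinder
    v_trap = p.setdefault("v_trap", 35 * k)
    v_c0 = p.setdefault("v_c0", 9.608 * k)
    v_c1 = p.setdefault("v_c1", 1.0 * k)
    v_c2 = p.setdefault("v_c2", 9.608 * k)
    electrodes = _cyl_wall_stack(R, [
        (0.0, z1, "central", "excitation", 0.0),
        (z1, z2, "compensation_0", "compensation", v_c0),
        (z2, z3, "compensation_1", "compensation", v_c1),
        (z3, z4, "compensation_2", "compensation", v_c2),
        (z4, z5, "trapping_rings", "trapping", v_trap),
        (z5, z6, "outer", "ground", 0.0),
    ], z6)
    return dict(
        electrodes=electrodes, R=R, z0=z4, rho0=R,
        symmetry="axisymmetric", axisymmetric=True,
        box=(R, z6), voltage_params=("v_trap", "v_c0", "v_c1", "v_c2"), params=p,
    )


def _ring_electrode(**p):
    R = p.setdefault("R", 0.0127)
    z0 = p.setdefault("z0", 0.0127)
    ring_unit = p.setdefault("ring_unit", INCH)  # unit behind "0.11/a, a = 1.875"
    n_rings = p.setdefault("n_rings", 5)
    width = 0.11 / 1.875 * ring_unit
    gap = 0.039 / 1.875 * ring_unit
    thick = p.setdefault("plate_thickness", 5e-4)
    volts = p.setdefault("ring_voltages", (0.2, 1.1, 2.0, 2.4, 2.8))
    electrodes = [
        *_cyl_wall_stack(R, [(0.0, z0, "wall", "excitation", 0.0)], z0),
    ]
    edges = [0.0]
    for i in range(n_rings):
        edges.append(edges[-1] + width)
        edges.append(edges[-1] + gap)
    for i in range(n_rings):
        r_in = 0.0 if i == 0 else edges[2 * i]
        r_out = edges[2 * i + 1]
        electrodes.append(
            ElectrodeSpec(
                f"ring_{i}", "trapping", float(volts[i]),
                lambda x, y, z, a=r_in, b=r_out, z0=z0, t=thick: (
                    (_rho(x, y) >= a) & (_rho(x, y) < b)
                    & (np.abs(z) >= z0) & (np.abs(z) < z0 + t)),
            )
        )
    outer = edges[2 * n_rings - 1] + gap
    electrodes.append(
        ElectrodeSpec(
            "endcap_ground", "ground", 0.0,
            lambda x, y, z, a=outer, R=R, z0=z0, t=thick: (
                (_rho(x, y) >= a) & (_rho(x, y) < R)
                & (np.abs(z) >= z0) & (np.abs(z) < z0 + t)),
        )
    )
    return dict(
        electrodes=electrodes, R=R, z0=z0, rho0=R,
        symmetry="axisymmetric", axisymmetric=True,
        box=(R, 1.3 * z0), voltage_params=("ring_voltages",), params=p,
    )


def paracell_leaf_halfwidth(z: np.ndarray, z0: float, N: int, beta: float) -> np.ndarray:
    """Angular half-width of a grounded leaf electrode at height z.

    The leaf width shrinks as 1 - z^2/z0^2, vanishing at the end caps; at
    z = 0 the grounded leaves cover the fraction beta of the circumference.
    """
    return beta * np.pi / N * (1.0 - (np.asarray(z) / z0) ** 2)


def _paracell(**p):
    R = p.setdefault("R", 0.0127)
    z0 = p.setdefault("z0", 2 * 0.0127)
    N = p.setdefault("N", 8)
    beta = p.setdefault("beta", 0.9)
    phi0 = p.setdefault("v_trap", 3.06)
    if N < 2:
        raise ValueError("paracell needs N >= 2 leaf electrodes")

    def leaf(x, y, z, R=R, z0=z0, N=N, beta=beta):
        r = _rho(x, y)
        th = np.mod(np.arctan2(y, x), 2 * np.pi / N)
        dist = np.minimum(th, 2 * np.pi / N - th)
        w = paracell_leaf_halfwidth(z, z0, N, beta)
        return (r >= R) & (np.abs(z) < z0) & (dist <= w)

    def biased(x, y, z, R=R, z0=z0, N=N, beta=beta):
        r = _rho(x, y)
        th = np.mod(np.arctan2(y, x), 2 * np.pi / N)
        dist = np.minimum(th, 2 * np.pi / N - th)
        w = paracell_leaf_halfwidth(z, z0, N, beta)
        return (r >= R) & (np.abs(z) < z0) & (dist > w)

    def endcap(x, y, z, R=R, z0=z0):
        return 2 * z**2 - (_rho(x, y)) ** 2 >= 2 * z0**2 - R**2

    electrodes = [
        ElectrodeSpec("leaves", "detection", 0.0, leaf),
        ElectrodeSpec("biased_wall", "trapping", phi0, biased),
        ElectrodeSpec("endcaps", "trapping", phi0, endcap),
    ]
    return dict(
        electrodes=electrodes, R=R, z0=z0, rho0=R,
        symmetry=f"N_fold:{N}", axisymmetric=False,
        box=(R, R, z0), voltage_params=("v_trap",), params=p,
    )


_BUILDERS = {
    "hyperbolic": lambda **p: _hyperbolic(False, **p),
    "hyperbolic_compensated": lambda **p: _hyperbolic(True, **p),
    "cuboid": _cuboid,
    "cubic": _cubic,
    "cylindrical": _cylindrical,
    "cylindrical_compensated": _cylindrical_compensated,
    "open_compensated": _open_compensated,
    "tolmachev": _tolmachev,
    "brustkern": _brustkern,
    "ring_electrode": _ring_electrode,
    "paracell": _paracell,
}

TRAP_KINDS = tuple(_BUILDERS)


def make_trap(kind: str, **overrides) -> TrapGeometry:
    """Build a cell design with reference parameters, optionally overridden.

    Raises ``ValueError`` for an unknown kind (listing the valid ones) and
    for non-positive lengths.
    """
    if kind not in _BUILDERS:
        raise ValueError(f"unknown trap kind {kind!r}; valid kinds: {', '.join(TRAP_KINDS)}")
    for name, v in overrides.items():
        if name in ("R", "z0", "a", "b", "c", "dz_c", "z_e", "dz1", "dz2",
                    "rho_max", "r_c", "ring_unit", "plate_thickness"):
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"length parameter {name!r} must be positive")
    spec = _BUILDERS[kind](**overrides)
    return TrapGeometry(kind=kind, electrodes=tuple(spec["electrodes"]),
                        R=spec["R"], z0=spec["z0"], rho0=spec["rho0"],
                        symmetry=spec["symmetry"], axisymmetric=spec["axisymmetric"],
                        box=tuple(spec["box"]), params=dict(spec["params"]),
                        voltage_params=tuple(spec["voltage_params"]))


def _axes_for(extent: float, spacing: float, symmetric: bool) -> np.ndarray:
    n = max(int(round(extent / spacing)), 8)
    if symmetric:
        return np.linspace(-extent, extent, 2 * n + 1)
    return np.linspace(0.0, extent, n + 1)


def default_spacing(geometry: TrapGeometry) -> float:
    """Production grid step, uniform in all directions.

    min(R, z0)/128 on axisymmetric grids (the paracell counts: its averaged
    field is solved on the reduced 2-D problem); min(R, z0)/64 for full 3-D
    Cartesian grids, where /128 would mean >10^7 unknowns.
    """
    n = 128 if geometry.axisymmetric or geometry.kind == "paracell" else 64
    return min(geometry.R, geometry.z0) / n


def rasterize(geometry: TrapGeometry, spacing: float | None = None,
              box: Sequence[float] | None = None) -> BoundaryGrid:
    """Rasterize electrodes onto a uniform grid; unclaimed box faces are grounded.

    Every node inside an electrode region carries that electrode's voltage;
    a node claimed by two electrodes is a geometry overlap and is rejected.
    """
    if spacing is None:
        spacing = default_spacing(geometry)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > min(geometry.R, geometry.z0) / 16:
        raise ValueError("spacing too coarse: must be <= min(R, z0)/16")
    box = tuple(box) if box is not None else geometry.box
    if any(b < g for b, g in zip(box, geometry.box)):
        raise ValueError("box does not enclose the electrodes")

    if geometry.axisymmetric:
        rho = _axes_for(box[0], spacing, symmetric=False)
        zax = _axes_for(box[1], spacing, symmetric=True)
        P, Z = np.meshgrid(rho, zax, indexing="ij")
        coords = (P, np.zeros_like(P), Z)
        axes = (rho, zax)
    else:
        x = _axes_for(box[0], spacing, symmetric=True)
        y = _axes_for(box[1], spacing, symmetric=True)
        zax = _axes_for(box[2], spacing, symmetric=True)
        X, Y, Z = np.meshgrid(x, y, zax, indexing="ij")
        coords = (X, Y, Z)
        axes = (x, y, zax)

    mask = np.zeros(coords[0].shape, bool)
    value = np.zeros(coords[0].shape)
    for e in geometry.electrodes:
        inside = e.region(*coords)
        if not inside.any():
            raise ValueError(f"electrode {e.label!r} contributes no node at this resolution")
        clash = inside & mask
        if clash.any():
            raise ValueError(
                f"geometry overlap: electrode {e.label!r} claims "
                f"{int(clash.sum())} node(s) already assigned")
        mask |= inside
        value[inside] = e.voltage
    # closed outer box: ground every unclaimed face node
    for ax in range(mask.ndim):
        for side in (0, -1):
            sl = [slice(None)] * mask.ndim
            sl[ax] = side
            sl = tuple(sl)
            if geometry.axisymmetric and ax == 0 and side == 0:
                continue  # rho = 0 is the symmetry axis, not a boundary
            face = mask[sl]
            value[sl][~face] = 0.0
            mask[sl] = True
    return BoundaryGrid(axes=axes, dirichlet_mask=mask, dirichlet_value=value,
                        axisymmetric=geometry.axisymmetric)


def paracell_averaged_boundary(geometry: TrapGeometry,
                               spacing: float | None = None) -> BoundaryGrid:
    """Axisymmetric boundary problem for the azimuthally averaged paracell field.

    The paracell's *domain* (cylinder wall plus axisymmetric end caps) is
    rotationally symmetric -- only the wall voltage pattern is not -- so
    azimuthal Fourier modes of the potential decouple exactly and the
    theta-averaged potential solves the 2-D axisymmetric Dirichlet problem
    whose wall value is the m = 0 component of the leaf pattern,
    phi0 (1 - beta (1 - z^2/z0^2)).
    """
    if geometry.kind != "paracell":
        raise ValueError("averaged boundary reduction applies to the paracell only")
    p = geometry.params
    R, z0, beta, phi0 = p["R"], p["z0"], p["beta"], p["v_trap"]
    if spacing is None:
        spacing = default_spacing(geometry)
    rho = _axes_for(R, spacing, symmetric=False)
    zax = _axes_for(z0, spacing, symmetric=True)
    P, Z = np.meshgrid(rho, zax, indexing="ij")
    mask = np.zeros(P.shape, bool)
    value = np.zeros(P.shape)
    wall = np.zeros(P.shape, bool)
    wall[-1, :] = True
    mask |= wall
    value[wall] = phi0 * (1.0 - beta * (1.0 - (Z[wall] / z0) ** 2))
    endcap = 2 * Z**2 - P**2 >= 2 * z0**2 - R**2
    mask |= endcap
    value[endcap] = phi0
    return BoundaryGrid(axes=(rho, zax), dirichlet_mask=mask,
                        dirichlet_value=value, axisymmetric=True)
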