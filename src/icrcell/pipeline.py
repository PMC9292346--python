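"""End-to-end comparative evaluation of the cell designs.

For each design the pipeline runs: geometry -> trapping field (analytic
series where one exists, numeric Laplace solve otherwise) -> azimuthal
average -> harmonic fit over the ion flight region -> eigenfrequency /
comet-formation analysis with the reference ion cloud, and emits one
machine-readable row per trap.

Sources:

* ``cuboid``, ``cubic``   -- exact box series, averaged in closed form;
* ``cylindrical``         -- exact Bessel series;
* ``paracell``            -- numeric by default (the analytic averaged field
  is exactly harmonic, so only the numeric solve resolves the residual
  anharmonicity of the finite geometry); the analytic source is available
  for cross-checks of A20;
* everything else         -- numeric axisymmetric solve.
"""

from __future__ import annotations

import logging
import time
import tomllib
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from . import field_analytic as fa
from .field_solver import solve
from .harmonic_analysis import (DEFAULT_FIT_REGION, DEFAULT_FIT_NODES,
                                HarmonicFit, azimuthal_average, fit_harmonics,
                                fit_lattice_potential)
from .ion_dynamics import IonCloudSpec, comet_time, eigenfrequencies
from .trap_geometry import (TRAP_KINDS, TrapGeometry, default_spacing,
                            make_trap, paracell_averaged_boundary, rasterize)

__all__ = ["EvaluationRow", "PipelineConfig", "evaluate_trap", "evaluate_all",
           "harmonic_fit_for", "TABLE_ORDER", "REPORT_SCHEMA_VERSION"]

log = logging.getLogger("icrcell")

REPORT_SCHEMA_VERSION = 1

#: Row order of the comparative table (the ring-electrode cell is evaluated
#: too but flagged non-reference: its frequency metrics have no published twin).
TABLE_ORDER = (
    "hyperbolic", "hyperbolic_compensated", "cuboid", "cubic", "cylindrical",
    "cylindrical_compensated", "open_compensated", "tolmachev", "brustkern",
    "paracell",
)

_ANALYTIC = {"cuboid", "cubic", "cylindrical"}

CSV_COLUMNS = ["trap", "A20n", "A40n", "A60n", "comet_time_s", "A20_V_m2",
               "C_V", "d_m", "omega_plus_rad_s", "source", "spacing_m",
               "residual_V", "rms_fit_residual_V", "reference", "schema_version"]


@dataclass(frozen=True)
class PipelineConfig:
    spacing: float | None = None      # None -> per-trap default min(R, z0)/128
    tol: float = 1e-10
    max_iter: int = 20000
    fit_region: tuple = DEFAULT_FIT_REGION
    fit_nodes: tuple = DEFAULT_FIT_NODES
    cloud: IonCloudSpec = field(default_factory=IonCloudSpec)

    @staticmethod
    def from_toml(path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        grid = doc.get("grid", {})
        fit = doc.get("fit", {})
        cloud = doc.get("cloud", {})
        kw = {}
        if "spacing" in grid:
            kw["spacing"] = grid["spacing"]
        if "tol" in grid:
            kw["tol"] = grid["tol"]
        if "max_iter" in grid:
            kw["max_iter"] = grid["max_iter"]
        if fit:
            kw["fit_region"] = (fit.get("rho_max", DEFAULT_FIT_REGION[0]),
                                fit.get("z_max", DEFAULT_FIT_REGION[1]))
            kw["fit_nodes"] = tuple(fit.get("nodes", DEFAULT_FIT_NODES))
        if cloud:
            kw["cloud"] = IonCloudSpec(**cloud)
        return PipelineConfig(**kw)


@dataclass
class EvaluationRow:
    """Machine twin of one comparative-table row."""

    trap: str
    A20n: float
    A40n: float
    A60n: float
    comet_time_s: float
    A20_V_m2: float
    C_V: float
    d_m: float
    omega_plus_rad_s: float
    source: str
    spacing_m: float | None
    residual_V: float | None
    rms_fit_residual_V: float
    reference: bool = True
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return asdict(self)


def _analytic_fit(geometry: TrapGeometry, config: PipelineConfig) -> HarmonicFit:
    p = geometry.params
    kind = geometry.kind
    if kind in ("cuboid", "cubic"):
        a = p["a"]; b = p.get("b", a); c = p.get("c", a)
        fn = lambda r, z: fa.cuboid_averaged(r, z, a, b, c, p["v_trap"])
    elif kind == "cylindrical":
        fn = lambda r, z: fa.cylinder_potential(r, z, p["R"], p["z0"], p["v_trap"])
    elif kind == "paracell":
        fn = lambda r, z: fa.paracell_averaged_potential(
            r, z, p["R"], p["z0"], p["beta"], p["v_trap"])
    else:
        raise ValueError(f"no analytic source for {kind!r}")
    avg = fit_lattice_potential(fn, region=config.fit_region, nodes=config.fit_nodes)
    return fit_harmonics(avg, region=config.fit_region, d=geometry.d,
                         nodes=config.fit_nodes)


def _numeric_fit(geometry: TrapGeometry, config: PipelineConfig):
    spacing = config.spacing or default_spacing(geometry)
    t0 = time.perf_counter()
    if geometry.kind == "paracell":
        # exact azimuthal-mode decoupling: the averaged field solves a 2-D
        # axisymmetric problem with the m = 0 wall voltage
        boundary = paracell_averaged_boundary(geometry, spacing)
    else:
        boundary = rasterize(geometry, spacing=spacing)
    grid = solve(boundary, tol=config.tol, max_iter=config.max_iter)
    log.info("%s: solved %s grid in %.2f s (residual %.2e V)", geometry.kind,
             "x".join(str(s) for s in grid.phi.shape), time.perf_counter() - t0,
             grid.residual)
    avg = azimuthal_average(grid)
    fit = fit_harmonics(avg, region=config.fit_region, d=geometry.d,
                        nodes=config.fit_nodes)
    return fit, spacing, grid.residual


def harmonic_fit_for(geometry: TrapGeometry,
                     config: PipelineConfig | None = None,
                     source: str = "auto") -> HarmonicFit:
    """Harmonic fit of a trap's averaged trapping field (analytic if possible)."""
    config = config or PipelineConfig()
    if source == "auto":
        source = "analytic" if geometry.kind in _ANALYTIC else "numeric"
    if source == "analytic":
        return _analytic_fit(geometry, config)
    return _numeric_fit(geometry, config)[0]


def evaluate_trap(kind: str, config: PipelineConfig | None = None,
                  source: str = "auto", overrides: dict | None = None) -> EvaluationRow:
    """Evaluate one design end-to-end and return its report row.

    ``source`` is ``auto``, ``analytic`` or ``numeric``.
    """
    config = config or PipelineConfig()
    stage = "geometry"
    try:
        geometry = make_trap(kind, **(overrides or {}))
        if source == "auto":
            source = "analytic" if kind in _ANALYTIC else "numeric"
        stage = f"field ({source})"
        spacing = residual = None
        if source == "analytic":
            fit = _analytic_fit(geometry, config)
        elif source == "numeric":
            fit, spacing, residual = _numeric_fit(geometry, config)
        else:
            raise ValueError("source must be auto, analytic or numeric")
        stage = "dynamics"
        tc = comet_time(fit, config.cloud)
        freq = eigenfrequencies(fit.A20, config.cloud)
    except Exception as exc:
        raise RuntimeError(f"evaluation of {kind!r} failed at stage {stage}: {exc}") from exc
    return EvaluationRow(
        trap=kind, A20n=fit.A20n, A40n=fit.A40n, A60n=fit.A60n,
        comet_time_s=tc, A20_V_m2=fit.A20, C_V=fit.C, d_m=fit.d,
        omega_plus_rad_s=freq.omega_plus, source=source, spacing_m=spacing,
        residual_V=residual, rms_fit_residual_V=fit.rms_residual,
        reference=kind != "ring_electrode")


def evaluate_all(config: PipelineConfig | None = None,
                 kinds=TABLE_ORDER, include_ring: bool = False):
    """Evaluate the comparative-table designs; per-trap failures do not abort.

    Returns (DataFrame, errors) where ``errors`` maps trap kind to the
    failure message for any trap that could not be evaluated.
    """
    rows, errors = [], {}
    all_kinds = list(kinds) + (["ring_electrode"] if include_ring else [])
    for kind in all_kinds:
        try:
            rows.append(evaluate_trap(kind, config).to_dict())
        except Exception as exc:  # report, keep going
            log.error("%s failed: %s", kind, exc)
            errors[kind] = str(exc)
    df = pd.DataFrame(rows)
    if len(df):
        df = df[CSV_COLUMNS]
    return df, errors


def write_report(df: pd.DataFrame, path) -> None:
    path = str(path)
    if path.endswith(".json"):
        df.to_json(path, orient="records", indent=2)
    else:
        df.to_csv(path, index=False, columns=[c for c in CSV_COLUMNS if c in df])
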