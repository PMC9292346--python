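# icrcell

Electrostatic evaluation of FT-ICR (Penning) measuring-cell designs.

In Fourier-transform ion cyclotron resonance mass spectrometry, ions orbit
in a strong magnetic field inside an ion trap (the "ICR cell") and are
detected through the image current they induce on detection electrodes.
The trap's electrostatic field is never perfectly harmonic, and the
imperfection has a direct analytical cost: the reduced cyclotron frequency
ω₊ becomes position dependent, an initially compact ion cloud dephases into
a "comet", and the signal — hence resolving power — collapses.  Much of the
half-century evolution of cell design (cubic → cylindrical → compensated →
dynamically harmonized) is a fight against this effect.

`icrcell` puts eleven historical cell designs through one common,
quantitative protocol, for instrument builders and simulation people who
want comparable numbers rather than per-paper conventions:

1. **Geometry** — each design (hyperbolic, compensated hyperbolic, cuboid,
   cubic, cylindrical, closed/open compensated cylinders, two multi-ring
   compensated variants, trapping-ring-electrode cell, dynamically
   harmonized cell) built as labelled electrodes with reference dimensions
   and voltages.
2. **Field** — exact eigenfunction series where they exist, otherwise a
   sparse-direct / conjugate-gradient Dirichlet–Laplace solver on
   axisymmetric or 3-D grids (red-black SOR included as a reference
   implementation).
3. **Harmonic content** — azimuthal averaging and least squares of

   φ̄(ρ,z) ≈ C + A₂₀(z² − ρ²/2) + A₄₀(8z⁴ − 24z²ρ² + 3ρ⁴) + A₆₀(16z⁶ − 120z⁴ρ² + 90z²ρ⁴ − 5ρ⁶)

   over the ion flight region (ρ, z ≤ 10 mm), reported dimensionally and
   normalized by d, d² = ½(z₀² + ½ρ₀²).
4. **Ion dynamics** — eigenfrequencies ω± = ωc/2 ± √((ωc/2)² − ωz²/2),
   the local ω₊(ρ,z), and the comet-formation time
   T = 2π/(max ω₊ − min ω₊) over a reference ion cloud (B = 7 T,
   m/z = 500, cloud radius 2 mm at 6 mm excitation radius, ±8 mm axially).
   Compensation analysis: the orthogonality factor
   γ = (V∂A₂/∂V_c)/(V∂A₄/∂V_c) and the aspect ratio where γ = 0.
5. **Detection** — reciprocity weight fields (Q = −qφ_w), the closed-form
   odd-harmonic content of cylindrical-cell signals (a 120° electrode nulls
   the third harmonic), and multielectrode frequency multiplication
   (p alternating pairs keep only orders p(2n+1): 8 electrodes detect at
   4ω₊).

See `docs/methods.md` for the model, conventions, numerical choices and
limitations.

## Worked example

```
$ icr eval --trap cubic --analytic
{
  "trap": "cubic",
  "A20n": 0.5200856931679938,
  "A40n": 0.00462229000508462,
  "A60n": -0.002907935773582534,
  "comet_time_s": 0.02471439562003615,
  "A20_V_m2": 4299.383662289408,
  ...
}
```

The 1-inch cubic cell at 1 V trapping voltage has a dimensionless trapping
curvature A₂₀ ≈ 0.52 and residual anharmonicities A₄₀ ≈ 4.6e-3,
A₆₀ ≈ −2.9e-3; across the reference cloud those spread ω₊ by about
250 rad/s, so the cloud dephases in ~25 ms — at 7 T the signal of a plain
cubic cell dies long before a high-resolution transient completes.  Running
`icr eval --trap paracell` instead gives a comet time of seconds: the
dynamically harmonized cell's averaged field is harmonic by construction,
which is exactly why that design took over high-field FT-ICR.

Detection harmonics for a four-electrode (two-pair) layout at half the cell
radius:

```
$ icr detect --pairs 2 --rho-over-r 0.5
order   amplitude/q
2       +1.591549e-01
6       -3.315728e-03
10      +1.243398e-04
...
```

Only orders 4n+2 survive — the detected frequency doubles, and so does the
resolving power per unit transient time.

Other entry points: `icr list-traps`, `icr eval-all --out table.csv`
(the full comparative table), and the library API (`icrcell.evaluate_trap`,
`icrcell.make_trap`, `icrcell.solve`, ...).

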