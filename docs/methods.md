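# Methods

## The model and its assumptions

The package models steady peristaltic transport in the wave frame of a
two-dimensional symmetric channel.  Assumptions: incompressible Jeffrey fluid
(linear viscoelasticity, relaxation-to-retardation ratio `λ₁`); sinusoidal
wall wave of amplitude ratio `ε` (`h(x) = 1 + ε sin 2πx`, period 1 in the
dimensionless axial coordinate); long-wavelength, low-Reynolds lubrication
limit (wavenumber `δ → 0`, `Re → 0`), which removes inertia, axial diffusion
and the normal-stress terms and makes the cross-stream pressure gradient
vanish; uniform magnetic field inclined at `β` acting on a conducting fluid
(damping `∝ M² cos²β` on the laboratory-frame velocity `u + 1`); Boussinesq
buoyancy coupling the temperature back into the momentum balance; viscous
heating and a uniform volumetric heat source entering the energy balance as
`η Br² θ`.

Boundary conditions at each station: `u = 0, θ = 0` on the centreline
`y = 0` and `u = −1, θ = 1` on the wall `y = h(x)`.  Note the centreline
condition is a velocity pin, not the symmetry condition `u'(0) = 0`; it is
the boundary-value problem this model poses, and all derived quantities
honour it.  The energy source is implemented as `η Br² θ` (the form the
printed temperature solution actually solves), not the `η Br θ` variant that
appears once in the unreduced equations.

## Parameters

| name | meaning | default | admissible |
|------|---------|---------|------------|
| `eps` | wall amplitude ratio | 0.5 | `0 ≤ eps < 1` |
| `M` | Hartmann number | 2.0 | `≥ 0` |
| `beta` | field inclination (rad) | π/6 | `|beta| < π/2` |
| `alpha` | channel inclination (rad) | π/4 | `[0, π/2]` |
| `lambda1` | Jeffrey ratio | 0.5 | `≥ 0` |
| `Br` | Brinkman number | 2.0 | `> 0` |
| `eta` | heat source/sink | 0.5 | `≥ 0` |
| `c1` | gravity group | 1.0 | `≥ 0` |
| `c2` | buoyancy group | 1.0 | `≥ 0` |
| `F` | wave-frame flow rate | −0.4 | any |

The defaults are package choices placed inside the ranges swept by the
figures of the source study (whose captions are not available); they are not
asserted to be that study's values.  `eps = 0.5` mirrors the study's stated
half-width/amplitude pair while keeping `h > 0` (equal half-width and
amplitude would pinch the channel shut).  Angles are radians throughout the
library; the CLI accepts degrees behind an explicit flag.  The legacy
geometry key `d` has no role in the reduced system and is accepted-but-
ignored in configs, with a warning.

Validation enforces the resonance guard `Br (1+eps) √eta < π`: the
temperature closed form contains `csc(Br h √eta)` and is singular when the
argument reaches π anywhere along the channel.  The guard is strict but not
padded, so nearly resonant configurations are admissible; the finite-
difference verifier additionally estimates the 1-norm condition of its
discrete temperature operator and refuses (condition `> 1e12`) rather than
return garbage.

## Closed-form evaluation: numerical choices

* The homogeneous velocity modes are evaluated as `sinh(m y)/sinh(m h)` and
  `sinh(m(h−y))/sinh(m h)` (`m = √a₁`) written with non-positive exponents
  only, so arbitrarily large Hartmann numbers cannot overflow; the boundary
  values are reproduced exactly in floating point by construction.
* The exponential-basis constants `c3, c4` are obtained by solving the 2×2
  boundary system (directly for `m h < 30`, by the algebraically identical
  overflow-safe expressions beyond).  A test confirms they agree with the
  published `c4` expression to 1e−10 relative — the printed constant is
  consistent with the boundary conditions.
* Small-argument path: for `Br² η h² < 1e−10` the temperature becomes the
  conduction profile `y/h` and the buoyancy particular term its polynomial
  limit.  This covers `η = 0` continuously.
* Degenerate magnetic limit: for `a₁ < 1e−8` the generic form (which contains
  `c_I/a₁`) is replaced, only on explicit request (`a1_limit=True`), by the
  exact `a₁ = 0` solution of `u'' = −c_I − a₂ θ`.  Without the flag a
  degenerate-configuration error is raised, so silent catastrophic
  cancellation is impossible.  The two branches agree to ~1e−6 at the
  crossover (`M ≈ 1e−4`).
* Flux, stream function and shear use term-wise closed-form antiderivatives
  and the analytic derivative — never numerical differencing or quadrature
  (those appear only as test oracles).

## Pressure gradient, pressure rise, friction

The flow rate is affine in `dp/dx` (the gradient enters only through `c_I`),
so the gradient realising a prescribed `F` is computed exactly from two flux
evaluations.  `Δp` and `F_λ` integrate `dp/dx(x)` and `−h² dp/dx(x)` by
composite 16-point Gauss–Legendre quadrature with panel doubling until two
successive estimates agree to 1e−9 (the integrands are smooth and periodic;
8–32 panels suffice).  The window defaults to `[0, 2π]`, the form in which
these integrals are conventionally quoted, although `h` has period 1 — so the
default window spans a non-integer number of wavelengths; `window="one"`
integrates over exactly one wavelength.  For `ε = 0` the two differ exactly
by the factor 2π.

The published pressure-gradient formula is implicit — its right-hand side
contains `c3, c4, c_I`, which depend on `dp/dx` — and, solved by damped
fixed-point iteration, it converges to a value that differs from the
flux-condition solution (e.g. by ≈ 0.78 at the defaults, `F = −0.4`,
`x = 0.3`).  The package therefore treats the flux condition as the
definition and emits the comparison as a structured discrepancy report
(`pressure_gradient_report`) instead of silently choosing.

`F` is defined as the wave-frame flux `∫₀ʰ u dy`; it is the only definition
consistent with the `(F + h)` grouping in the published gradient formula and
with standard peristalsis usage.

## Streamline topology and bolus quantification

`Ψ(x, y) = ∫₀ʸ u dy'` with `Ψ(x, 0) = 0`; the wall is then a streamline with
`Ψ(x, h(x)) = F` identically (verified to 1e−8 in tests, and in fact exact to
rounding).  Fields are sampled on a body-fitted grid: uniform `x` over one
period (endpoint excluded), uniform `σ = y/h(x)` per column, default
129×129.  Because the model reports only qualitative bolus sizes, an
operational definition is fixed: marching-squares contours of `Ψ` at 41
evenly spaced levels strictly between min Ψ and max Ψ; closed contours
touching neither wall are grouped into nested families (containment test on
the contour polygons); the outermost contour of each family is one bolus
region, with shoelace area, polygon centroid and interior Ψ extremum.  The
ψ-field is tiled over two periods before contouring and each region is
counted once through a one-period centroid window, so boluses straddling the
periodic seam are captured whole.  Bolus areas change by < 1 % when the grid
is refined 129 → 257.

Trapping window: at the default parameters Ψ is monotone in `y` at every
station for `F ≲ −0.3` (its range is exactly `[F, 0]`), so no closed
streamlines exist at the package's general-purpose default `F = −0.4`.  The
trapping studies therefore run at `F = −0.1`, chosen from a flow-rate scan as
mid-window (trapping appears for `F ≳ −0.25` and persists to positive `F`);
the value is recorded in every bolus output header.  Whether the source
study's streamline figures fixed `F` or `Δp` is not stated; fixed `F` is used
and documented.

One figure sweep is ambiguous in the source: the symbol swept in its first
streamline figure is printed as the "heat source/sink β" although β is
elsewhere the field inclination.  The sweep here treats it as the field
inclination (values 0–0.5 rad), which acts through `a₁ ∝ cos²β` and
reproduces the reported shrinking bolus; an `eta` sweep remains available
through the generic sweep machinery for the alternative reading.

The Brinkman-number bolus sweep of the source runs to `Br = 7`, which at the
default `η = 0.5` violates the resonance guard (`7 · 1.5 · √0.5 > π`); the
package's documented Br sweep therefore uses `η = 0.05`, the largest round
value keeping `Br = 7` well inside the guard.

## Finite-difference verifier

Second-order central differences on a uniform grid over `[0, h]`; θ is
solved first (tridiagonal direct solve), then u with the discrete θ as
source — mirroring the one-way coupling of the reduced system and reusing
none of the closed-form algebra.  Equations are assembled in dy²-scaled form
(rows O(1)), so the reported `residual_norm` is a clean backward error,
< 1e−10 after the solve.  Observed convergence order is 2.0 ± 0.2 over
n ∈ {201, 401, 801, 1601}; at n = 4001 the truncation error is ~1e−8 for
moderate parameters, comfortably inside the 1e−6 verification tolerance.
The verifier's shear check differentiates the FD velocity with a five-point
(fourth-order) stencil; its flux check uses the trapezoid rule.  Randomized
verification draws restrict the Hartmann/Jeffrey ranges (`M ≤ 1.8`,
`λ₁ ≤ 1`) so that the solution's fourth derivative (`∝ a₁²`) keeps the FD
truncation error below the tolerance; wide-range draws exercise the
overflow-safe closed form in the boundary-condition tests instead, up to
`M = 12` (and a dedicated test to `M = 1000`).

## Profile studies

Velocity/temperature/shear profile sweeps are evaluated at a fixed imposed
pressure gradient, `dp/dx = 0`, isolating the body-force-driven motion (with
the default `c₁ sin α ≈ 0.71` the forcing constant `c_I` is then positive for
every `λ₁`).  Whether the source study's profile figures fixed `dp/dx` or `F`
is not stated; the fixed-gradient choice is documented here and in the output
headers.

## What the qualitative checks do and do not show

The acceptance suite asserts the source study's reported directions at the
documented defaults.  The ones this model actually exhibits, and which pass:
midpoint velocity decreasing in `M`, increasing in `α` and `c₁`; temperature
increasing in `Br` and `η` (provably, for `k h < π`); signed shear increasing
in `M`; friction trend opposite to the pressure-rise trend for `M`, `Br`,
`α`, `c₁`; bolus area non-increasing in `β`.

The following reported directions are *not* properties of the printed model
at fixed flow rate, and their acceptance tests are intentionally left
failing rather than weakened:

* **Pressure rise vs `α`, `c₁`**: with `F` fixed, the flux condition pins
  `c_I`, so `dp/dx = c₁ sin α − c_I/(1+λ₁)` and
  `∂Δp/∂(c₁ sin α) = +2π > 0` — an increase, for every `F`, where a decrease
  is reported.
* **Pressure rise vs `M`, `λ₁`, `Br`**: the measured directions at `F = −0.4`
  are opposite to the reported ones; because the affine `Δp(F)` lines for
  different parameter values cross, these directions flip with `F`, so the
  report may describe a different part of the pumping plane.
* **Friction opposition for `λ₁`**: both `Δp` and `F_λ` decrease with `λ₁`
  at `F = −0.4`.
* **Bolus area vs `M` over {0, 0.1, 0.5, 0.8}**: non-monotone (grows to
  `M = 0.5`, drops ~7 % at 0.8; the interior Ψ extremum shows the same), and
  vs `Br` over {1, 3, 5, 7} at `η = 0.05`: flat to slightly decreasing.  The
  `β` sweep — equivalent to lowering the effective Hartmann number from 2 —
  does match, consistent with the area increasing in effective `M` near 2
  but not on [0, 0.8].

All synthetic configurations here are the analytic model itself; no real
physiological data enters, so passing tests demonstrate internal consistency
of the solution and its numerics, not agreement with measured flows.

## Known limitations

* The unreduced equations (finite `δ`, `Re`, the `λ₂` retardation terms and
  normal stresses) are documentation only; neither the closed forms nor the
  verifier solve them.
* The constitutive law implemented is the Jeffrey shear stress actually
  printed in the source's equations; a true Rabinowitsch (cubic shear) law is
  out of scope.
* No cross-stream velocity reconstruction beyond the stream function; no
  Lagrangian particle advection or reflux analysis; no Biot-number effects.
* Negative `η` (a genuine heat sink, giving a `sinh` temperature profile) is
  rejected rather than solved.
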