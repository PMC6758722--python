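# Methods

`iptsl` simulates intraperitoneal (IP) chemotherapy of a spherical solid
tumor, in two delivery modes: conventional free doxorubicin instilled into
the peritoneal cavity, and doxorubicin encapsulated in thermosensitive
liposomes (TSL) whose release is triggered by mild hyperthermia from a
focused-ultrasound (HIFU) transducer. This note records the model, the
numerical choices, and the judgement calls, in that order.

## Physical model

**Geometry.** A sphere of radius `R` (2, 5 or 10 mm presets) with an
avascular necrotic core of radius `Rn = R/2`, embedded in normal tissue for
the thermal problem. Everything is axisymmetric about the ultrasound beam
axis, which passes through the tumor center.

**Interstitial flow.** Darcy flow `v = -kappa grad(P_i)` with the Starling
filtration source `phi_B = L_P (S/V) [P_B - P_i - sigma_s (pi_B - pi_i)]`
in the vascularized rim, `phi_B = 0` in the core, no functional lymphatics,
and `P_i = 0` on the tumor surface. Because the source is affine in `P_i`
the steady problem is a single linear solve. Two scales follow directly
from the defaults: the effective filtration pressure
`P_e = 1470 Pa` (the attainable maximum of `P_i`) and the screening length
`1/alpha = sqrt(kappa / (L_P S/V)) = 267 um`, which sets the thickness of
the pressure boundary layer and hence of the outward-convection barrier.

**Drug compartments.** Four concentration fields (mol·m⁻³ tissue):
encapsulated `C_L` (TSL mode), free `C_F`, receptor-bound `C_B`,
internalized `C_I`:

- mobile species advect with `v` and diffuse (`D_F` for free drug from the
  solute table; `D_L` for liposomes from Stokes-Einstein with Ogston
  fiber-matrix retardation `D_L = D0 exp(-sqrt(phi_f)(1 + a/a_f))`);
- transvascular loss uses the Patlak/pore form with zero plasma
  concentration, `Phi = -(P_eff S/V) C Pe/(e^Pe - 1)` with
  `Pe = phi_B (1 - sigma_f)/(P_eff S/V)`; the pore model (Renkin hindrance
  `H(lambda)`, partition `(1-lambda)^2`) gives `P_eff` and `sigma_f` from
  the particle/pore radius ratio, with the pore-area factor calibrated once
  so the free-doxorubicin permeability equals its measured value;
- release `k_EL(T) C_L` feeds `C_F`, with `k_EL` piecewise-linear in
  temperature between tabulated knots (0.00417 s⁻¹ at 37 °C to 0.05409 s⁻¹
  at 42 °C, constant above);
- binding `(1/phi) K_ON C_rec C_F <-> K_OFF C_B` with a constant receptor
  pool, and irreversible internalization `K_INT C_B -> C_I`.

Both the transvascular exchange and the forward binding term are applied
per unit *accessible* fluid volume (divided by `phi = 0.3`). This is a
deliberate convention choice (flag `phi_divides_transvascular`): treating
all exchange terms in the same volume convention is self-consistent, and it
sets the free-drug loss rate to `~0.2 s⁻¹`, i.e. a penetration length
`sqrt(D_F/k) ≈ 41 um` and a half-width of ~29 um — the regime the model is
meant to describe. Without the division the length is 74 um; nothing else
changes qualitatively.

**Acoustics.** Linear monochromatic propagation: the field of the bowl
transducer (70 mm aperture, 20 mm central hole, 62.64 mm focal length) is
the Rayleigh-Sommerfeld integral over the spherical cap with a complex
wavenumber `k = omega/c + i alpha_abs(f)` for absorption,
`alpha_abs = 8.55 Np m⁻¹ MHz⁻¹ × f`. Nonlinearity and acoustic diffusivity
are neglected; below ~2 MPa focal pressure their contribution to the
heating term is a few percent, and the temperature controller renormalizes
the deposition anyway. Heating: `q = 2 alpha_abs I`, `I = p²/(2 rho c)`.

**Bioheat.** Pennes equation with region-wise constants, 37 °C initial and
far-field conditions, zero perfusion in the necrotic core, and an Arrhenius
perfusion-shutdown factor `D_P = exp(-int A_f exp(-dE/(R T)) dt)`
(`A_f = 1.98e106 s⁻¹`, `dE = 6.67e5 J/mol`; at 43 °C held for 10 min,
`D_P ≈ 0.93`). A PI controller (`K_p = 0.2`, `K_i = 0.01`) scales the
acoustic deposition to hold the domain-maximum temperature at
`T_set = 43 °C`; the output is clamped at zero with a frozen integrator
(anti-windup). Probe location and set point are configuration choices; the
domain maximum is the conservative reading of "keep the tumor below 43 °C".

**Cell kill.** `FK = 1 - exp(-omega C_I)` with `omega = 0.6603 m³/mol`,
evaluated on the tumor-volume mean of `C_I` (a pointwise-then-average
variant is provided; by concavity of the survival map it can only be
smaller). Exposure is quantified by trapezoidal AUCs of the mean `C_F` and
`C_B`; penetration by `W_1/2`, the interpolated depth at which the total
concentration along an inward ray falls to half its surface value (the
default total includes `C_L` — drug carried at depth is drug at depth; a
toggle excludes it and both are logged).

A structural identity worth knowing when interpreting FK: because
internalization is linear, the mean internalized drug is exactly
`C̄_I(T) = K_INT × AUC_B` (AUC in mol·m⁻³·s), so
`FK = 1 - exp(-omega K_INT AUC_B)`. FK is therefore *rigidly* tied to
`AUC_B` — with the default `K_INT = 5e-5 s⁻¹` an hour-long exposure with
`AUC_B ≈ 21 mol·m⁻³·s` can never kill more than ~0.07% of cells,
independent of mesh or averaging. Reported kill fractions orders of
magnitude above this level imply an internalization constant near
`5e-3 s⁻¹`; `k_INT` is exposed in the configuration for such sensitivity
studies, but the shipped default stays at the tabulated value.

## Discretization

**Mesh.** Spherical-polar `(rho, theta)` finite volumes, axisymmetric in
azimuth, cell-centered. The tumor surface and the necrotic interface lie
exactly on radial faces; interface continuity is then automatic in the
flux form. The radial mesh is graded: 7.5 um cells in a 0.6 mm band at the
surface (resolving both the ~30 um drug layer and the 267 um pressure
layer), geometric coarsening (ratio 1.25) to 250 um inside, and growth to
2.5 mm in the normal-tissue extension. Default 24 polar cells. The thermal
domain radius is `max(4R, R + 25 mm)`: for small tumors a bare `3R` margin
would place the fixed-temperature boundary inside the focal ellipse
(~11 mm long at 1 MHz) and bias the heating. Grid metrics (volumes, face
areas) are exact for the solid of revolution; the discrete tumor volume
equals `(4/3)pi R³` to rounding. A planar-2D metric is available behind
`numerics.planar` for sensitivity checks only.

**Flow.** Sparse direct solve; relative residual checked below 1e-6
(typically 1e-14). Face velocities by two-point differences; the surface
velocity uses the Dirichlet face value. Verified against the closed-form
two-region solution to 2e-4 relative L∞ at default resolution.

**Transport.** Implicit Euler, default `dt = 1 s`, first-order upwind
advection (conservative flux form plus a `+phi_B C` diagonal source so the
non-conservative advection form of the governing equations is recovered),
central diffusion. The operator of each mobile species is constant in
time, so one LU factorization per species serves the whole run. Local
kinetics are closed-form per-cell implicit solves, wrapped around the
transport step in symmetric (Strang) halves. The release source is *not*
split: the exact exponential decay of `C_L` over the step supplies a
per-cell released amount that enters the implicit `C_F` solve as a source,
which removes the splitting bias that the stiff near-boundary cells would
otherwise amplify (tumor-mean fields move by <0.2% between `dt = 1 s` and
`dt = 0.25 s`). The scheme is an M-matrix: concentrations cannot go
negative. A running mass audit (boundary influx minus transvascular loss
versus stored mass) closes to rounding and is checked below 1% in tests.
Verified against dense matrix-exponential integration of the identical
semi-discrete system on a 20-cell instance (<0.1% per compartment at
`dt = 0.1 s`) and against the spherical erfc diffusion front with all
sinks disabled (<2%).

**Bioheat.** Implicit conduction (one factorization per time-step size),
explicit perfusion and source (stable: perfusion rate ~0.02 s⁻¹). Time
steps 0.1 s during the controller ramp (first 100 s), 0.5 s to 300 s, then
2 s; the controller acts every step. Temperature snapshots every 30 s are
linearly interpolated in time by the transport solver. The discrete energy
audit closes to rounding; controller overshoot stays below 0.5 °C after
the ramp. Verified against the free-space heat kernel (<2%).

**Acoustics.** Source quadrature at 4 points per wavelength in both cap
directions; refinement doubling moves the focal pressure by <1e-5 and an
automatic check rejects non-converged quadratures (>0.5%). Verified
against the exact on-axis annular-bowl solution (<0.1%).

## What the scenario generator does and does not emulate

Scenarios are fully synthetic: ideal spheres, homogeneous region-wise
parameters, a fixed-concentration cavity reservoir, a constant receptor
pool, and a stationary flow field. Passing tests therefore demonstrate
correctness of the stated transport/thermal physics, not fidelity to real
peritoneal tumors, which have irregular shapes, heterogeneous perfusion
and ECM, cavity clearance and redistribution of the instillate, lymphatic
uptake of liposomes, thermally induced changes in vessel permeability, and
acoustic heterogeneity along the beam path. None of those are modeled.
Plasma drug concentration is identically zero (no systemic recirculation),
so transvascular exchange is a pure loss.

## Known limitations

- First-order upwinding smears steep fronts; the graded surface band keeps
  this acceptable for the ~30 um half-widths of interest, and `W_1/2` is
  computed from interpolated profiles.
- The perfusion term is Pennes-like (distributed heat sink); discrete
  vessel cooling and thermally increased perfusion are not represented,
  and `D_P` only ever decreases.
- With the tabulated release rates and hindered diffusivities, liposome
  penetration lengths are `sqrt(D_L/(k_EL + vessel loss)) ≈ 10-35 um`;
  encapsulation relocates drug deposition to the heated border rather than
  deepening it. Order-of-magnitude penetration gains would require larger
  effective diffusivities or convective enhancement not present in this
  model.
- The controller holds the *maximum* temperature at 43 °C; with a wide
  focal ellipse (0.5 MHz) parts of the cavity-facing boundary approach
  release-active temperatures, which the model reports but does not
  penalize.
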