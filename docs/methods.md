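# Methods

`mwablate` simulates interstitial microwave ablation (MWA) of hepatic tumors
with a multi-slot coaxial applicator. The modeling chain is

1. a frequency-domain electromagnetic (EM) solve of the antenna field in
   tissue,
2. the specific absorption rate (SAR) and volumetric heat source derived from
   that field,
3. a transient bioheat solve with temperature-dependent material properties
   and vaporization,
4. an Arrhenius damage integral, from which perfusion shutdown, the necrotic
   zone, tumor coverage and collateral damage follow.

The loop is closed: heating collapses the tissue's dielectric properties,
which changes the field, so the EM problem is re-solved as the temperature
evolves.

## Electromagnetic model

The antenna and surrounding tissue are bodies of revolution, so the vector
Helmholtz equation

∇²**E** − μ_r k₀² (ε_r − j σ/(ω ε₀)) **E** = 0

reduces to a scalar problem for the azimuthal magnetic field H_φ(r, z)
(axisymmetric TM formulation). The discrete unknown is u = r·H_φ: the
coaxial TEM mode (H_φ ∝ 1/r) is then *exactly* linear in r, which removes
the dominant interpolation error of nodal elements inside the feed line. The
weak form is

∫ (1/ε̃) ∇u·∇w (1/r) dr dz − ω²μ₀ ∫ u w (1/r) dr dz = boundary terms,

with ε̃ = ε₀(ε_r − jσ/(ωε₀)) piecewise constant per element (evaluated from
the local region and element-mean temperature). Boundary conditions:

- **Port** (coax cross-section at the feed): first-order TEM port condition
  ∂u/∂n + jk_d u = 2 jk_d A, where A is set so the incident time-averaged
  power equals the requested input power, P = π Z_d A² ln(b/a). The
  reflection coefficient S11 is the projection of the scattered port field
  onto the TEM mode (a diagnostic only; no impedance optimization is done).
- **Outer boundary**: first-order absorbing condition with the local complex
  wavenumber. In liver at 2.45 GHz the attenuation is ~50–60 Np/m, so the
  default 30–40 mm of lossy tissue damps residual reflections; the power
  balance (absorbed + radiated + reflected vs input) closes to well under 2%
  at default resolution and is asserted in the tests.
- **Metal** (conductors, shorted tip): perfect conductors; E_t = 0 is the
  natural boundary condition of the H-based formulation.
- **Axis**: u = r H_φ = 0.

Phasors carry peak amplitudes with the exp(+jωt) convention, so the
dissipated power density is Q_ext = σ|E|²/2 and SAR = σ|E|²/(2ρ). First-order
(P1) triangles are used throughout with mesh refinement near the antenna;
the guided-wave attenuation oracle (tissue-filled line vs the closed-form
plane-wave decay constant) verifies 1% accuracy at the default resolution.

## Antenna and geometry

The applicator is a parametric multi-slot coax: 10 slots of width 0.6 mm at
0.8 mm spacing cut in the outer conductor near the tip (slot count, width and
spacing configurable). Coax radii are not part of the published parameter
set; defaults (inner a = 0.14 mm, dielectric b = 0.47 mm, b/a ≈ 3.35) give
~50 Ω with a PTFE filling. The outer conductor is a 0.1 mm metal sheath; the
tip is a shorted metal plug that closes both the coax and the catheter
channel, so the slots are the only apertures. A plastic catheter
(r = 0.895 mm) jackets the antenna.

The tip sits at z = 0 with the feed below (z = −insertion_depth); tissue
fills z > 0 and everything outside the catheter. Meshes are graded
structured triangulations whose grid lines snap to every material interface,
so each cell carries exactly one region tag; the curved tumor boundary is
classified by cell midpoints (volume error is quadratic in h; <1% at the
default fine size, asserted in the tests).

Tumors are either analytic ellipsoids or imported closed surface meshes
(STL/OFF/PLY via trimesh). Axisymmetric runs use the volume-preserving
ellipsoid of revolution (semi-axes √(ab), c); `coverage_3d` additionally
samples the revolved damage field inside the true 3-D shape to quantify the
2-D-vs-3-D approximation. Default probe placement advances the tip so the
tumor's distal face lies 6 mm beyond it — ablation zones extend proximally
along the shaft, so this mirrors clinical guidance of placing the tip at the
distal tumor boundary and is what makes full coverage attainable for
elongated tumors.

## Bioheat models

Three backends share one axisymmetric P1 discretization:

- **Pennes** (default):
  (ρc)_t ∂T/∂t = ∇·(k_t ∇T) + β ρ_b ω_b c_b (T_b − T) + Q_ext + Q_m, with
  arterial blood fixed at 37 °C and the perfusion-shutdown coefficient β
  supplied by the damage module (step model: β = 0 once Ω ≥ 1; a smooth
  β = e^(−Ω) variant is selectable).
- **LTNE**: two-temperature porous-media model; tissue and blood phases with
  volume fractions (1−ε)/ε exchange heat through a lumped interfacial
  conductance h_c·a plus the perfusion term; the blood phase advects with a
  constant Darcy-scale velocity u and carries its own vaporization branch.
- **LTE**: the single-temperature limit with effective capacity
  (1−ε)(ρc)_t + ε(ρc)_b and advection ε(ρc)_b β u·∇T. The published
  combined equation carries an extra (1−ε) factor on the effective
  conductivity that is *not* produced by summing the two LTNE equations; the
  default follows the combined equation as printed, and a `mixture` mode
  ((1−ε)k_t + εk_b without the extra factor) is exposed — the LTNE→LTE
  stiff-coupling check uses that mode, since the limit is a statement about
  the two-equation system.

ω_b = 6.4·10⁻³ 1/s, ε = 0.1, h_c·a = 10⁵ W/(m³·°C) and u = 0 are external
literature defaults (they are not part of the published parameter table);
every acceptance-level property is either independent of them or phrased as
a model limit. Q_m defaults to 0: metabolic heat is negligible against
microwave deposition.

### Vaporization

Two treatments are selectable:

- **Effective specific heat** (default): c′ = c − α ∂W/∂T with the tissue
  water mass fraction W(T) (three branches: slow exponential drawdown
  70–100 °C, steep linear drop 100–104 °C, exponential tail above) and
  α = 2.26·10⁶ J/kg. W is extended as a constant below 70 °C, and branch
  derivatives use the left limit at the joins, keeping c′ finite and
  deterministic. The printed form of the effective-heat correction is
  dimensionally ambiguous about a density factor; the default reads W as a
  mass fraction (c′ in J/(kg·°C)); the alternative reading is exposed as
  `effective_heat_mode="as_printed"`.
- **Enthalpy method**: (ρc)(T) piecewise — liquid product below 99 °C, a
  latent spike h_fg·C_w/ΔT across the 99–100 °C band (ΔT = 1 °C), gas-phase
  ρ_g c_g above. Gas-phase constants (ρ_g = 370 kg/m³, c_g = 2160 J/(kg·°C))
  are external literature defaults.

### Time integration

Implicit Euler with a fixed step (default 1 s). The transient term uses a
nodal lumped cumulative enthalpy H(T) (the exact integral of the apparent
heat capacity), and each step solves the nonlinear system

M_i (H(T_i) − H(T_i^n))/Δt + (K T)_i + (P T)_i = F_i

by damped Newton with a residual line search. H is strictly increasing, so
the solution is unique; Newton remains robust when nodes cross the
vaporization band within one step, where fixed-point (Picard) iteration
oscillates. Convergence tolerance is 10⁻³ °C on the increment; a step that
stalls above 5 °C raises with the residual. The LTNE two-field system uses
damped Picard on the same chord (secant) capacity.

Lumped mass matrices are used throughout: they preserve the discrete maximum
principle on the non-obtuse structured triangulations and conserve total
enthalpy exactly for insulated, source-free problems (both asserted). The
outer tissue boundary is Dirichlet 37 °C; the symmetry axis and the
antenna–tissue interface are adiabatic. The antenna interior is excluded
from the thermal domain (no active cooling; the catheter contact is modeled
as no-flux, the standard closure for non-cooled applicators).

### EM–thermal coupling cadence

The EM problem is re-solved when the temperature anywhere has drifted more
than 5 °C since the last solve, or after 30 simulated seconds, whichever
comes first. Outside the vaporization band the dielectric sigmoids change
slowly, so this keeps the number of EM solves per 600 s run at a few tens.

## Temperature-dependent dielectrics

ε_r(T) = s1·(1 − 1/(1 + e^(s2 − s3·T))) and σ(T) = r1·(1 − 1/(1 + e^(r2 −
r3·T))) model the dielectric collapse as water is driven off. The
coefficients are not printed in the source parameter set; the healthy-liver
defaults (s = 48.391, 6.286, 0.0764; r = 2.173, 5.951, 0.0697 at 2.45 GHz)
are the fits used across the hepatic-MWA modeling literature, and the tumor
amplitudes scale the healthy ones by the reported body-temperature contrast
(+24% permittivity, +11% conductivity). Tests assert the contrast intervals
and monotone decrease rather than any exact collapse shape.

## Damage, coverage and optimal power

Ω(t) = ∫ A e^(−ΔE/(R T_K)) dt with A = 7.39·10³⁹ 1/s and
ΔE = 2.577·10⁵ J/mol (the standard liver coagulation kinetics; external
provenance), accumulated by the rectangle rule at the thermal step — exact
for the solver's piecewise-constant-in-time temperatures. Ω ≥ 1 (necrotic
fraction 1 − 1/e) is the complete-ablation criterion; the smooth necrotic
fraction θ = 1 − e^(−Ω) is exported so intermediate iso-damage levels are
reproducible, and the 60 °C lethal isotherm is tracked alongside.

Isocontours are linear-interpolation level sets per triangle; enclosed
volumes are exact revolved integrals of the clipped superlevel polygons, so
coverage (fraction of tumor volume with Ω ≥ 1), collateral volume (healthy
tissue with Ω ≥ 1) and the 60 °C volume are consistent with the FEM fields.

The optimal input power is the smallest power whose end-of-run coverage
reaches the target (default 1.0), found by bisection on the monotone
coverage-vs-power map and verified post hoc by fresh runs at P* and
P* − tol.

## Synthetic data generator

`make_fixtures` writes ellipsoid tumor surfaces at the three emulated
patient extents (1.64 × 1.71 × 3.81 cm, 1.74 × 1.53 × 2.10 cm,
1.78 × 1.97 × 2.27 cm), a "lumpy" variant of each (seeded smooth
low-frequency radial perturbation, ±6%, emulating irregular patient tumors),
and matching YAML configs; output is byte-identical for a fixed seed. The
generator emulates tumor size and bulk shape only — it does not reproduce
vascular heterogeneity, perfusion gradients, tissue anisotropy, or the
non-axisymmetric tumor/antenna arrangement of real patient anatomy, so
passing tests demonstrate correctness of the modeling chain on idealized
geometry, not clinical predictive accuracy.

## Problem sizes and numerical defaults

Default production mesh: h_fine = 0.35 mm near the antenna/tumor, graded to
3 mm (≈40 000 triangles); dt = 1 s; 600 s ablations. The validation suite
and the packaged tests use a coarsened configuration (h_fine = 0.9 mm,
≈6 000 triangles, dt = 2.5 s) so the complete suite — including a four-point
power sweep and the bisection with post-hoc verification — runs on one CPU
in minutes; the properties being asserted (oracle agreement, monotonicity,
bracketing) are resolution-independent statements and hold at both scales.

## Known limitations

- The 2-D axisymmetric reduction cannot represent triaxial tumors or
  off-axis antenna placement; `coverage_3d` documents (but does not remove)
  the approximation.
- The first-order absorbing boundary and P1 elements trade accuracy for
  simplicity; the power-balance and attenuation oracles bound the resulting
  error at default resolution.
- |S11| of the default antenna is a diagnostic; no matching network or
  choke is modeled, so absolute deposited power at a given input power is
  design-specific.
- Above ~110 °C the tissue model (desiccated dielectrics, gas-phase heat
  capacity) extrapolates published curves; carbonization chemistry is not
  modeled.
- LTNE blood-phase vaporization uses the same latent spike as tissue; the
  two-field Picard solver is robust only while blood stays below the
  vaporization band in practice.
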