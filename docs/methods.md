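# Methods

## Physical model

**Electric field.**  At 470 kHz the displacement current in tissue is
small compared with the conduction current, so the field problem is
quasi-static and purely resistive: ∇·(σ∇V) = 0 with V = V₀ on the
electrode surfaces, V = 0 on the outer surfaces of the tissue block
(monopolar drive against a distant ground), and n·J = 0 on any
non-grounded boundary.  Relative permittivity is carried in the
material table as metadata but never enters the solve.  The volumetric
Joule source is Qr = σ|E|².

Because σ is temperature-independent (the material table gives
constants and no σ(T) law is part of the model), the problem is linear
in the drive voltages.  The solver therefore computes one *unit-voltage
basis potential* per electrode — 1 V on that electrode, 0 V on the
others and on ground — once per geometry, and every later field state
is a superposition.  A 120 s controlled ablation costs one basis solve
plus cheap recompositions.

**Heat transport.**  Temperature obeys transient conduction–advection
with the Joule source:

ρc ∂T/∂t = ∇·(k∇T) − ρc v_z ∂T/∂z + Qr.

No perfusion or metabolic term is included; intra-arterial blood flow
is the only blood-cooling mechanism, consistent with specifying a
single luminal inlet velocity.  The block's outer surfaces are held at
the far-field temperature (Dirichlet), and blood enters the lumen at
that temperature.  The luminal velocity profile is Poiseuille
(v(r) = 2·v_mean·(1 − (r/R)²)); a plug profile is available.

**Control.**  The generator is modeled as an incremental PI loop on the
squared amplitude u = a² (proportional to delivered power):
u ← clamp(u + kp·Δe + ki·e·dt), e = setpoint − probe, clamped to
[0, a_max²] and to a per-electrode power ceiling; clamping the command
is the anti-windup.  Each electrode's probe is the mean temperature of
the tissue cells face-adjacent to it (a voxel rendering of a surface
thermocouple; a max-based probe is config-selectable).  The default
mode regulates each electrode independently, matching a multi-channel
generator that reports per-electrode power/temperature/impedance
traces; a common-amplitude mode (single source voltage on all
electrodes, driven by the hottest probe) is also provided.

## Discretization and numerics

* Uniform cell-centered Cartesian voxel grid, artery axis along z,
  SI units internally; mm at the config boundary.  Default spacing
  0.5 mm (production desk-scale); 0.25 mm supported where the ~8×
  cost is acceptable.
* 7-point finite volumes with harmonic-mean face conductivities (σ and
  k), which keeps fluxes continuous across material jumps.  Boundary
  Dirichlet data acts through half-cell face conductances.
* The electrodes are equipotential Dirichlet regions; gold's metallic
  σ enters only through the face conductances, which is numerically
  equivalent to not resolving the metal interior.
* **Joule source**: accumulated per face as G_f·ΔV_f² and attributed to
  the two adjacent cells in proportion to each cell's share of the face
  resistance.  This face-based source makes the discrete energy balance
  Σᵢ aᵢIᵢ = ∫Qr dV exact up to solver tolerance (the electrode-metal
  share is ~σ_tissue/σ_gold ≈ 10⁻⁸ and is zeroed).  Central-difference
  |E| and |J| fields are provided for reporting; they are not used as
  the heat source because one-sided stair-boundary gradients do not
  conserve discrete energy.
* **Linear solves**: Jacobi-preconditioned conjugate gradients to a
  1e-8 relative residual for the Laplace basis; each backward-Euler
  step solves a strongly diagonally dominant system with warm-started
  BiCGSTAB (rtol 1e-10), falling back to GMRES and then a direct solve
  on the rare breakdowns of degenerate (advection-only) systems.  All
  paths are deterministic: identical configs reproduce traces
  bit-identically.
* **Time integration**: backward Euler, dt = 0.1 s (unconditionally
  stable; the luminal CFL number is ≈200, far beyond any explicit
  scheme).  Controller cadence 0.1 s.
* **Advection**: first-order implicit upwind in *advective* form,
  ρc·v·(T_c − T_below)/h per cell.  The rasterized flow field is not
  discretely divergence-free where electrode cells interrupt the lumen;
  the advective form keeps zero row sums there regardless, preserving
  constants and the discrete maximum principle.  (A conservative
  face-flux form was tried first and rejected: at flow convergences it
  pumped spurious enthalpy, violating the maximum principle.)  The
  scheme's numerical diffusion along z is v·h/2 — orders of magnitude
  above the physical α in the lumen core — so luminal temperatures are
  qualitative; the lumen's role here is to cool the wall, which it does
  at the right bulk rate (enthalpy flux ρc·Q·ΔT is resolution-
  independent).
* Temperatures above 110 °C abort the run: the model has no
  vaporization or charring physics and is outside its validity there.

## Electrode geometry (the one unprinted input)

The basket's electrode dimensions are not published.  Defaults: six
rectangular gold patches, 1.5 mm (axial) × 1.0 mm (circumferential) ×
0.15 mm (radial), apposed to the lumen wall at 0°,60°,…,300°, with a
1.0 mm axial pitch (a helical ribbon spanning 5 mm, consistent with the
6–8 mm band a gel phantom shows).  All dimensions are config-exposed.
Rasterization widens the radial band to at least one cell so the
0.15 mm foil stays representable at 0.25–0.5 mm grids; a patch that
still rasterizes to zero cells raises a resolution error.  At 0.5 mm
spacing the per-electrode cell count varies with angle (4–6 cells);
at 0.25 mm the six footprints are balanced to within ±20%.

## Controller gains

kp = 3 V²/°C and ki = 0.8 V²/(°C·s) (with a 30 V amplitude ceiling and
15 W per-electrode power ceiling) were chosen so the 60 °C setpoint is
attained at ≈25–30 s with no overshoot beyond 0.1 °C — the trajectory
shape a temperature-controlled RDN generator exhibits, with the probe
in the low-50s °C mid-ramp at 5 s.  The ramp portion is
gain-dependent and treated as qualitative.

## Lesion metrics

All metrics are computed on the running-maximum temperature field:
thermal damage (and the phantom gel's color change) is irreversible, so
any historical exceedance of the 45 °C threshold counts.

* **Injury depth** — maximum Euclidean distance from the electrode
  *surface* (electrode cells treated as exact axis-aligned boxes) over
  threshold-exceeding cells of stationary media.  The flowing lumen is
  excluded: blood that once exceeded 45 °C is advected out of the
  artery within a fraction of a second and is not injured tissue; with
  upwind numerical diffusion it would otherwise register a spurious
  many-millimetre "depth" along the downstream wall.
* **Coverage / continuity** — the running-max field is resampled
  (trilinear) onto a cylindrical shell at lumen radius + 0.5 mm (the
  peri-adventitial onset of the renal nerves; config-exposed), binned
  into 360 × 1° sectors; a sector is covered if the threshold is
  exceeded at any axial position.  Continuity is connected-component
  analysis of the covered set on the unrolled (θ, z) shell with
  θ-periodicity: continuous ⇔ one component spans all angular bins.
  Gap intervals are reported wrap-aware.
* **Band dimensions** — axial width and radial depth beyond the lumen
  wall of the extraluminal lesion (cell-center convention), matching
  how a cut gel block is read with a ruler.

## What the presets do and do not emulate

The presets are complete stand-ins for the study conditions — every
input is a printed parameter, a stated condition, or a documented
default above.  They do not emulate: basket wires and catheter shaft,
vessel wall thickness, tissue inhomogeneity, σ(T)/k(T) dependence,
perfusion, pulsatile or non-axial flow, electrode–tissue contact
resistance, or vaporization.  Passing tests therefore show that the
*model* reproduces the published electro-thermal behaviour, not that
the model captures every feature of a living artery.

Two reproduction targets are genuinely out of reach of this model class
and are reported as computed rather than forced:

* **360° coverage by 30 s.**  With the default (undocumented) electrode
  size, blood-cooled wall tissue midway between adjacent electrodes
  peaks 1–2 °C below the 45 °C threshold on the default shell, leaving
  three gaps totalling ≈34°: simulated coverage at 30 s is 326°
  (90.6%), which in fact matches the published *abstract* coverage
  figure of 91.99% rather than the stronger "360° in 30 s" claim.
  The patch dimensions are config-exposed, and they are decisive:
  widening the circumferential arc from 1 mm to 2 mm yields 360°
  continuous coverage by 30 s in the same scenario.
* **In-vivo 120 s depth.**  The simulated 45 °C boundary reaches
  4.0 mm from the electrode surface at 120 s (2.5 mm at 30 s, 3.3 mm
  at 60 s), ≈20% short of the published 5.08 mm endpoint.  Everything
  unprinted pushes this down: the assumed small electrode patches, the
  cell-center localization of the isotherm (up to half a cell), and
  the choice of a 37 °C Dirichlet thermal outer boundary (no thermal
  boundary condition is published; an insulated block would run
  hotter).
* **Phantom depth 3–6 mm from the channel wall.**  An upper bound shows
  this cannot follow from a 60 °C surface in 25 °C gel: even with the
  *entire* channel wall held at 60 °C forever, steady cylindrical
  conduction to the 25 °C block boundary puts the 45 °C isotherm
  2.6 mm beyond the wall.  The 120 s transient with small electrodes
  reaches 1.4 mm.  The published band was plausibly measured from the
  channel axis (3–6 mm from the axis ≡ 0–3 mm beyond the wall,
  consistent with the published 6–8 mm width); this package reports the
  wall-referenced value.

## Problem sizes

Production runs use the 26 × 26 × 30 mm block at 0.5 mm spacing
(52 × 52 × 60 ≈ 162k cells), 1200 implicit steps per 120 s run —
about 5 min (in vivo) / 3 min (phantom) on one core.  Unit and property
tests run on reduced boxes (≈13 × 13 × 15 mm) and handmade voxel
fixtures; the concentric-sphere oracle uses a 20 mm box at 1.0/0.5/0.25
mm spacings and validates the 1/r form to <2% with first-order
convergence, with the voxelized conductor's ±h/2 radius ambiguity
accounted for explicitly.
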