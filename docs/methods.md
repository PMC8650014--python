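# Methods

`nasopulse` simulates micron-aerosol delivery through the nose under
*bi-directional* flow — air enters one nostril, turns 180° behind the closed
soft palate, and leaves through the other nostril — either at a steady flow
rate or with a superimposed sinusoidal pulsation. It is a desk-scale model:
every component runs on one CPU in minutes, and the geometry is a
parameterized surrogate rather than a patient airway. This note records the
model, its assumptions, the parameters that matter, and what results on the
surrogate do and do not say about real noses.

## Surrogate geometry

The airway is a swept tube: a circular cross-section, optionally corrugated
as `r(θ) = r0 (1 + a cos Nθ)`, swept along a planar centerline composed of
straight and circular-arc segments with a twist-free frame. The
bi-directional surrogate is

    inlet nosepiece (45° tilt) → right channel → 180° U-bend →
    left channel → outlet nosepiece (45°),

with a smooth "nasal valve" constriction (radius ratio 0.5 over 12 mm) near
the entry of each channel. The corrugation (12 lobes, amplitude 0.52 of the
7 mm channel radius) is the stand-in for the turbinate folds: it gives the
cavity a large epithelial area at a small hydraulic diameter. Corrugation is
ramped to zero through the vestibules and valves.

Two dorsal wall patches on the U-bend outer wall are labelled as the
olfactory regions. Their areas are *pinned* to the reference values
(right 330 mm², left 337 mm²) by accumulating triangles outward from a
dorsal seed point until the target area is reached, so the patch areas are
exact to one-triangle granularity regardless of mesh resolution. The default
channel length (110 mm) and corrugation amplitude were then fixed so the
total-wall to olfactory area ratio is ≈ 64, matching the anatomical ratio
the deposition-per-area bookkeeping depends on. All meshes are watertight
(every edge shared by exactly two triangles) and carry a named patch per
triangle; patch areas always sum to the total area to 1e-12 relative.

Voxelization fills the mesh bounding box (two-cell margin) with an isotropic
grid, classifying cell centers by ray parity along a slightly tilted ray
(the tilt resolves rays through triangle edges; the watertight guarantee
makes parity meaningful). Isolated speckle components below 1 % of the
inside cells are dropped; a larger split raises a resolution error. The LES
filter width is the cell size, Δ̃ = V_cell^{1/3} = dx.

## Prescribed flow

The momentum equation is *not* solved. The base velocity field on the voxel
grid follows the duct geometry analytically. In chart coordinates
(arclength s, azimuth θ, normalized radius η):

    u = f(η) (Q / A(s)) · [ T̂ + η (∂r_wall/∂s) ρ̂ / h ],
    h = 1 − κ(s) ρ cos θ,

with `f(η) = 2(1−η²)` (laminar parabolic profile; the channel Reynolds
number at 4 L/min is ≈ 230) or `f = 1` (plug), A(s) = π r0²(1+a²/2) the
local section area, and κ the signed centerline curvature. The radial term
keeps streamlines attached to the tapering wall (valve, nosepiece blends);
the metric factor h makes streamlines follow bends exactly, so a tracer
never drifts into the wall of a curve. The field conserves volumetric flow
along the duct; its residual divergence on the grid is the discretization
error of this construction. Cells outside the fluid receive the value of
the nearest inside cell so that near-wall interpolation does not spuriously
decelerate parcels before the geometric wall test.

**Pulsation** uses the inlet law `U(t) = U0 (1 + sin 2πft)` with f = 45 Hz
(period 22.2 ms); its mean over whole periods is exactly U0. The unsteady
field is modelled quasi-steadily: the base field is multiplied by the
instantaneous waveform factor. The Womersley number at 45 Hz in a 7 mm
channel is ≈ 24, so true oscillatory flow would have thin Stokes layers and
phase lag that this approximation drops — a stated model limitation.

**Valve-jet closure.** A provable property of pure quasi-steady scaling is
that tracer pathlines are identical for steady and pulsatile flow (time is
merely reparameterized), so pulsation could not change deposition patterns
at all in that model — contrary to what resolved simulations of this flow
show, where the post-valve jet impinges on the dorsal wall under steady flow
and is disrupted and moderated by the oscillation. That mechanism is
therefore *prescribed*: the surrogate base field carries a dorsal jet
component downstream of the inhalation-side valve (peak 0.01 of the
valve-throat mean speed, Gaussian window σ = 30 mm centered 55 mm past the
throat, parabolic radial profile, directed along the local dorsal frame
vector), and in pulsatile mode its strength is attenuated to 0.3 of the
steady value. The direction of the pulsation effect on deposition is thus an
assumption of this closure, not a prediction; only its bookkeeping
consequences (how much deposition moves where) are computed. The attenuation
factor and jet shape are model parameters, set once and recorded here.

Default air properties: ν = 1.5e-5 m²/s, μ = 1.8e-5 Pa·s, ρ = 1.2 kg/m³
(room temperature), all configurable.

## Parcel transport

Each computational parcel carries a statistical weight ω (physical particles
per parcel); weights are set so the injected physical mass is exact. Parcels
obey

    dx/dt = u_p,   du_p/dt = (u_s − u_p)/τ_p + g,
    τ_p = ρ_p d_p² / (18 μ f_d),

with the Schiller–Naumann drag factor `f_d = 1` (Re ≤ 1),
`1 + 0.15 Re^0.678` (1 < Re ≤ 1000), `0.44 Re/24` (beyond) — the reading of
the correlation that is continuous-in-regime and reduces to Stokes drag at
low Reynolds number. The gas velocity seen by a parcel is the trilinear
interpolation of the grid field at its position, frozen over the sub-step;
no stochastic dispersion model is added (for 1 µm particles on a fine grid
the modelled fluctuations are negligible, and the particle equations carry
drag and gravity only). With frozen coefficients the sub-step ODE is linear
and is integrated *exactly*:

    u(Δt) = u* + (u0 − u*) e^{−Δt/τ},   u* = u_s + τ g,
    x(Δt) = x0 + u* Δt + τ (u0 − u*)(1 − e^{−Δt/τ}),

which is unconditionally stable and accurate for any Δt/τ — the time step is
limited only by how fast u_s varies along the trajectory. The step is
Courant-limited, `Δt = C dx / max|u|` with C = 0.9, rescaled each step by
the instantaneous waveform factor and never coarser than 1/40 of the
pulsation period. An additional τ/5 cap is available (`adaptive_dt`'s
`tau_min`) for integrators that are not exact in τ; the driver does not
apply it by default because the analytic update needs no sub-τ resolution —
at 1 µm it would force ~3 million steps for no accuracy gain.

Parcels are injected uniformly in time over the 0.5 s window and uniformly
over the inlet disc, activating with the instantaneous local gas velocity.
They stick to the wall on first contact (earliest segment–triangle
intersection per sub-step, deterministic (fraction, triangle-index)
tie-break, voxel-binned candidate search) and escape when they cross the
inlet/outlet caps or leave the grid box. Mass is partitioned exactly into
deposited + escaped + airborne; the balance closes to better than 1e-12
relative on every run (it is a bookkeeping identity, checked continuously).

A consequence of prescribing the flow on a voxel grid is that parcels
travelling within ~one cell of the corrugated wall can be captured by it:
the interpolated field cannot resolve the sub-cell wall-parallel motion
inside the turbinate-like folds, so near-wall parcels graze and stick,
preferentially just downstream of the inhalation-side valve where the folds
begin. Quantitatively this capture plays the role that impaction on the
uneven mucosal surface plays in resolved simulations; it is a property of
the model (documented, resolution-dependent), not a calibrated term.

## Two-way coupling

The injected 2.5 mg of unit-density aerosol in the ~50 cm³ surrogate gives
a particle volume fraction of ~5e-5, above the 1e-6 threshold where two-way
momentum coupling is conventionally engaged. Each step the drag reaction is
deposited on the grid with trilinear kernel weights G_l:

    S_u[l] = −(1/V_l) Σ_p G_l(x_p) ω_p F_D,p,   F_D,p = m_p (u_s − u_p)/τ_p,

so Newton's third law, Σ_l S_u[l] V_l = −Σ_p ω_p F_D,p, holds to machine
precision by construction. Because the gas momentum equation is not solved
here, the source is computed and reported every step (and can optionally
perturb the velocity seen by the parcels as ũ += S Δt/ρ); full feedback
would require the momentum solver and is out of scope.

## Subgrid-scale diagnostics

The localized dynamic k-equation closure is implemented as standalone field
operators on gridded velocity: filtered strain rate (central differences,
one-sided at box edges), a 3³ top-hat test filter at width Δ̂ = 2Δ̃
(truncated-stencil average at boundaries, hence linear and
constant-preserving), the Germano resolved stress
L_ij = tf(u_i u_j) − tf(u_i) tf(u_j), the scale-similarity prefactor

    M = Δ̃ √k · tf(|S̃|) − 2Δ̂ √(tf k) · |tf(S̃)|,   |S̃| = (2 S̃:S̃)^{1/2},

and the dynamic coefficients Ck = ⟨L_ii M⟩/⟨M M⟩ and
Cε = ⟨ξ m⟩/⟨m m⟩ with ξ = L_ii, m = (tf k)^{3/2}/Δ̂ − tf(k^{3/2}/Δ̃), where
⟨·⟩ is the 3³ test-filter average. As printed in the source model the
similarity term is scalar-valued; both contraction conventions are exposed
(`convention="scalar"` contracts against the trace of L and is the default
— it is dimensionless and invariant under u → λu, k → λ²k — while
`"tensor"` forms M·S̃_ij and contracts fully). Coefficients are clipped to
Ck ∈ [0, 0.5], Cε ∈ [0.5, 5] (backscatter excluded for robustness) and fall
back to the standard one-equation constants (0.094, 1.048) where the
identity degenerates (vanishing numerator or denominator: uniform or
quiescent fields). k_SGS is advanced explicitly (first-order upwind
advection, conservative face-averaged eddy diffusion, pointwise
production/dissipation, clipped at zero) under advective and diffusive
stability checks. The resolution index M = k_res/(k_res + k_SGS) ∈ [0, 1]
uses k_res = ½⟨|u − ⟨u⟩_t|²⟩_t over a caller-chosen snapshot window and is
defined as 1 where both energies vanish; the usual adequacy bands
(M ≥ 0.8, the 0.77–0.85 recommendation, M ≥ 0.99) are reported as cell
fractions.

## Ventilation tracer

The drug-laden-air fraction C (0 = resident air, 1 = inhaled air) obeys an
advection–diffusion equation with total diffusivity ν/Sc + ν_SGS/Sc_SGS
(defaults Sc = Sc_SGS = 0.7, air-like tracer; the closure's Schmidt numbers
are not constrained by the source study and are configurable). The update is
first-order upwind advection plus conservative central diffusion with the
diffusivity inside the divergence (so scalar mass is conserved for spatially
varying eddy viscosity; for uniform diffusivity this reduces to the
constant-coefficient Laplacian form), zero-flux walls, and C = 1 held on the
inlet cells. Under its stability bound the scheme is monotone, which yields
two provable properties checked in the tests: C ∈ [0, 1] always, and every
region's volume-weighted mean is non-decreasing in time. Reported metrics:
volume-weighted regional means, iso-volume fractions with C above 0.5 and
0.99, and the percentage of the inlet flow crossing a region's oriented
section (midpoint quadrature of ∫u·n dA on a point lattice at dx/2 spacing).

## Endpoints

Deposition efficiency is the percentage of injected mass deposited per
region; regional DEs over a disjoint exhaustive partition sum exactly to the
whole-domain DE. Dose per area (ng/mm², 100 % drug loading assumed) is the
deposited patch mass divided by the patch area, so dose × area recovers the
mass exactly. Ratio tables report right/left ratios per run and
steady/pulsatile fold changes per region, with division by zero mapped to an
infinity marker; displayed ratios use three significant figures. The
impaction parameter IP = d²Q (µm²·L/min) indexes DE sweeps; on the bend
benchmark (tube radius 2.5 mm, bend radius 12.5 mm, 90°, 15 L/min,
diameters 1–20 µm) DE increases strictly with IP.

## What the surrogate does and does not show

The synthetic geometry preserves the *topology* of bi-directional delivery
(one flow path, valve constrictions, the 180° turn, a small dorsal olfactory
patch far from the inlet jet axis) and the printed area bookkeeping (330/337
mm² olfactory patches, 64:1 cavity-to-olfactory area ratio) — so DE/dose
*arithmetic*, conservation properties, and *directional* statements
(pulsation lowers total deposition under the jet-attenuation closure;
olfactory DE is orders of magnitude below total DE; the inhalation side
dominates) are meaningful on it. It does not preserve patient anatomy,
turbulence-resolving flow structure, or meatus-level flow partitioning, so
absolute regional DEs, the specific right/left ratios of a given nose, and
olfactory flow fractions are *not* comparable to patient-specific values and
are never asserted against them.

## Numerical sizes and determinism

Default grid: dx = 0.8 mm (≈ 93 000 fluid cells on the surrogate; dx must
stay below a quarter of the narrowest channel radius). Default library
parcel count 10⁴ (configurable up to the 4-million reference scale); the
shipped test suite runs the paired steady/pulsatile experiments at 5 000
parcels and the acceptance script at 6 000, sizes chosen so a full
reproduction completes in minutes on one CPU while olfactory deposits still
contain tens of parcels. Every random choice (injection times/positions)
flows from one integer seed through `numpy.random.default_rng`; identical
configuration and seed reproduce results bit-for-bit, including written CSV.
Geometry construction is deterministic. Wall-hit ties are broken by
(fraction, triangle index); interpolation at cell centers returns stored
values exactly; trilinear interpolation reproduces affine fields to 1e-12.

## Known limitations

- Prescribed quasi-steady flow: no pressure coupling, no resolved
  turbulence or secondary flows; the pulsation effect enters only through
  the jet-attenuation closure and the waveform scaling.
- Near-wall capture on the corrugated wall is grid-resolution dependent.
- No Brownian diffusion of particles (the particle equations carry drag and
  gravity only), no hygroscopic growth, no particle–particle interaction,
  no mucociliary clearance or absorption.
- The two-way source is reported, not fed back through a momentum solve.
- Olfactory flow fractions on the surrogate measure flow through a dorsal
  pocket of a smooth bend and are structurally larger than those of a
  recessed olfactory cleft.
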