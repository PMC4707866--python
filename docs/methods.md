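# Methods

This note records the scientific and numerical choices behind the
package: the model equations and their unit conventions, where each
parameter value comes from, what the reference scenarios emulate, and
the known limits of what passing tests demonstrate.

## Model structure and unit basis

The clot is a fibrous porous medium characterized per location by the
amount of lysed fibrin L. All bound-phase quantities — L, the fibrin
content n₀, the binding-site densities θ_α and the adsorbed
concentrations S_α — are expressed in µM **per initial fibre (solid)
volume**, a fixed reference basis with solid fraction φ₀; free
concentrations C_α are µM per fluid volume. The conserved amount of a
species per total volume is therefore ε·C_α + φ₀·S_α, and the free-phase
balance reads d(εC_α)/dt = −φ₀(A_α − Φ_α) + R_α with A the adsorption
rate and Φ the solubilization flux. This basis is what lets a clot whose
fibres occupy ~1% of its volume hold 34.9 µM of plasminogen in the bound
phase while the pore fluid carries 1.65 µM.

Closing the mass balance of that equilibrium (2 µM plasminogen loaded
into the pore fluid, partitioned with K_d = 38 µM) *determines* the
initial voidage: ε₀ = 34.9/(34.9 + 0.35) ≈ 0.9901, i.e. a fibre-internal
protein density of ≈ 28 mg/ml for a 0.28 mg/ml clot. ε₀ ≈ 0.99 is the
accepted porosity scale of coarse plasma clots, so the calibrated value
doubles as a physical sanity check.

## Microstructure maps

Homogeneous radial shrinkage: fibrin mass per unit fibre length scales
with R_f², hence R_f(L) = R_f0·√(1 − L/n₀) with R_f0 = 250 nm. Voidage
ε = 1 − φ₀(R_f/R_f0)². Binding sites track the remaining fibrin mass,
θ_α ∝ (R_f/R_f0)² (a surface-area ∝ R_f alternative is exposed as
`theta_scaling_exponent`). Permeability uses the Davies correlation for
fibrous beds, k = R_f²/(16 φ^1.5 (1 + 56 φ³)), capped at
k_max = 10⁻⁶ m²; cells whose voidage exceeds 0.9999 (≈ 99% lysed) drop
their Darcy resistance entirely, representing full recanalization. The
intact-clot permeability that results, k₀ ≈ 3.9·10⁻¹² m², sits in the
upper literature range for coarse clots.

## Kinetic parameter set

The dissociation constants follow the classical porous-clot lysis
lineage: tPA 0.58 µM, PLG 38 µM, PLS 0.057 µM. On-rates are 0.1 µM⁻¹s⁻¹
for tPA and 0.01 µM⁻¹s⁻¹ for PLG/PLS — adsorption equilibrates within
seconds, far below the lysis time scale, and the smaller PLG on-rate
keeps the explicit kinetics sub-step of the spatial tiers economical
without moving any equilibrium. Surface plasmin generation uses
k₂ = 0.3 s⁻¹, K_M = 0.16 µM (fibrin-templated activation); the
validation parameter set switches to K_M = 2.42 µM, k₂ = 0.22 s⁻¹ with a
5.88 µM (2 mg/ml) clot, the thin-film assay condition.

Three constants are not published to our precision and were calibrated
once against the model's own anchor observables, then frozen:

* θ_PLG0 (10 sites per monomer) and the fibre protein density — set by
  the 1.65/34.9 µM plasminogen partition of a 2 µM load;
* θ_tPA0 (0.06 sites per monomer) — keeps free tPA near its 50 nM dose
  while bound tPA reaches the ~0.4 µM scale;
* k_cat = 12 s⁻¹ with γ = 10 cuts (so k_cat/γ = 1.2 s⁻¹) — complete
  (99%) lysis of the reference clot at ≈ 90 s. The lysis clock is
  self-limiting (solubilization strips bound plasmin as lysis
  accelerates), scaling as (k_cat·k₂)^(−1/2).

α₂-antiplasmin enters the well-mixed tier only (1 µM, k_AP =
10 µM⁻¹s⁻¹, the 10⁷ M⁻¹s⁻¹ literature scale); the spatial tiers carry
tPA/PLG/PLS alone, since with solubilized plasmin promptly rebinding or
leaving, free-phase inhibition barely moves the lysis time.

Diffusivities are D = 10⁻¹⁰ m²/s for all three proteins. Values much
above this destroy the experimentally observed front regime (the clot
lyses near-uniformly); values at 5·10⁻¹¹ remain front-like but slow the
late-time homogenization of free tPA. Both ends of that range put the
1-D front velocity inside the 20–50 µm/min literature band.

## Numerics

**Well-mixed tier** — stiff adaptive integration (LSODA, rtol 10⁻⁸).
The solubilization singularity at L → n₀ is regularized by flooring the
remaining fibrin at 10⁻⁶·n₀; with κ = 1 the bound/site occupancy ratio
is invariant under solubilization, so S_α ≤ θ_α holds structurally and
every bound concentration reaches zero exactly at complete lysis.

**1-D tier** — explicit central-difference diffusion (safety factor 0.4
on dx²/2D), operator-split against sub-stepped explicit kinetics; the
sub-step is 0.5 divided by an a-priori bound on the fastest local rate
(~12 s⁻¹ at reference parameters). Dirichlet inlet at the clot face
(50 nM tPA, 2 µM PLG), zero-gradient outlet. The reference clot is
4.5 mm (domain 5.5 mm, 220 cells): long enough that the 10–80 min
velocity window and the 90 min snapshot stay inside the steady
propagation phase at ~35 µm/min; the dose-sweep scenario uses 6 mm for
the same reason at 1 µM. Front velocity is insensitive to clot length in
this regime, and halving dx moves it by far less than 5%.

With a consuming front, the raw spatial variance of free tPA *rises*
until full lysis (the profile is a supply-limited ramp whose variance
grows with its extent) and decays only on the slow L²/D clock
afterwards. The monotone signature of "free tPA approaching the uniform
inlet level" is its RMS distance from that level, which decreases across
all snapshots; that is the quantity the tests assert.

**Flow tier** — staggered (MAC) grid; monolithic steady solve of
momentum + continuity by sparse LU with Picard iteration on first-order
upwind convection. The Darcy term (µ/ρk ~ 10⁶ s⁻¹ in an intact clot)
sits on the diagonal, so the solve is immune to its stiffness — the
reason a pseudo-transient marching scheme was rejected. Fixed pressures
at the inlet/outlet faces, no-slip impermeable walls via ghost
reflection (wall error O(dy²)). Continuity is satisfied to direct-solver
precision, including a prescribed per-cell volume source.

**Coupled tier** — backward-Euler implicit transport (upwind advection,
central diffusion) with the LU factorization reused between flow
updates, so the post-breakthrough jet imposes no CFL limit; kinetics are
sub-stepped per cell as in 1-D, restricted to clot columns. The flow is
re-solved quasi-steadily whenever any cell's lysed fraction has changed
by 0.02 since the last solve (at least 30 s apart); a voidage-based
trigger would be ineffective here because the total voidage excursion is
only 1 − ε₀ ≈ 0.01. The continuity source is −∂ε/∂t (forward
difference), the lysis mass sink; its magnitude (≤10⁻⁵ s⁻¹) is
negligible for the flow but kept for bookkeeping. Default channel:
5 mm height, 2.5 mm clot, 10 mm upstream (4 clot widths, keeping the
supply to the clot face advective) and 12.5 mm downstream for the
recanalization jet, at 150×30 cells (~0.17 mm, 15 cells across the
clot). Doubling the resolution moves the breakthrough duration by ~4%.

## Reference scenarios and what they show

The shipped scenarios reproduce the canonical observables: the ~90 s
well-mixed lysis clock; the 1.65/34.9 µM plasminogen partition; a 1-D
lysis front that accelerates briefly and then advances linearly
(R² > 0.99) at 20–50 µm/min, with bound tPA/plasmin peaks that decay and
widen; dose–response velocities that flatten logarithmically from 1 nM
to 1 µM; and 2-D recanalization that initiates on the centerline, opens
a funnel-shaped canal widest at the proximal face, stays mirror-
symmetric at 1 Pa, breaks through monotonically faster from 1 to 20 Pa
(≈ 4000 s down to ≈ 350 s onset-to-breakthrough), and develops
monotonically larger distal recirculation zones.

## Limitations

* Uniform initial clot properties: no lytic fingering, no stochastic
  fragmentation or embolization, no platelets/red cells, no thrombin
  regeneration, no exposure of fresh binding sites by cleavage.
* The steady, symmetry-preserving flow solver does not spontaneously
  break the expansion-jet symmetry at high pressure drops; asymmetric
  recirculation would require an unsteady solver or an explicit
  perturbation, so symmetry-difference tests are stated as inequalities.
* With the Davies permeability, the post-breakthrough mural remnant
  perfuses and dissolves by BTR ≈ 1.3–1.6; experimental remnants can
  persist longer. Matched-BTR comparisons are therefore made at the
  developed (peak) recirculation rather than at late BTR checkpoints.
* Transport uses first-order upwinding: numerical dispersion ~u·dx/2 is
  comparable to D near the jet. Breakthrough orderings and symmetry
  metrics are robust to this; fine-structure concentration contours are
  not grid-converged at the default resolution.
* Blood is Newtonian and laminar; geometry is a 2-D channel.
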