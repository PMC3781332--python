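# Methods

## Model summary

The simulator couples three fields at steady state:

1. **Tissue PO₂** on a vertex-centered structured grid over the tissue box
   (x = width 216 µm, y = flow 532 µm, z = depth 500 µm; the chamber acts
   on z = 0). Reaction–diffusion with Michaelis–Menten consumption
   M(P) = M₀P/(P+P_cr) and myoglobin-facilitated diffusion in divergence
   form with arithmetically face-averaged S′_Mb (the coefficient is
   smooth; harmonic averaging makes no measurable difference).
2. **Capillary SO₂** per vessel on 50 axial segments, first-order upwind
   in the flow direction, blood PO₂ tied to saturation through the Hill
   curve, wall exchange j = κ(P_b − P_w) with the tissue sampled through
   per-segment wall maps.
3. **Plasma ATP** per vessel on the same axial grid, upwind convection,
   SO₂-linear erythrocyte release H_T·C₀(1 − C₁S) and endothelial wall
   degradation (2/R)k_d[ATP]. Nothing feeds back from ATP to oxygen, so
   ATP is solved after the O₂ fixed point is reached; the sequential
   solve is exact at steady state.

Internally lengths are cm, PO₂ mmHg, ATP mol/cm³ (reported as mol/L).
O₂ amounts are ml O₂, so solubilities (α = 3.89 × 10⁻⁵ ml O₂ ml⁻¹ mmHg⁻¹)
close the unit system.

## Parameters

Defaults are the rat-EDL parameter set: D = 2.41 × 10⁻⁵ cm²/s,
M₀ = 1.5 × 10⁻⁴ ml O₂ ml⁻¹ s⁻¹, P_cr = 0.5 mmHg, c_Mb = 1.02 × 10⁻²,
D_Mb = 3 × 10⁻⁷ cm²/s, P₅₀ = 37 mmHg, n = 2.7, P₅₀,Mb = 5.3 mmHg,
C_Hb = 0.52, v_rbc = 1.45 × 10⁻² cm/s, H_T = 0.19, H_D = 0.20,
C₀ = 1.4 × 10⁻⁹ mol s⁻¹ cm⁻³, C₁ = 0.891, k_d = 2 × 10⁻⁴ cm/s, capillary
entrance SO₂ 0.65. Erythrocyte/plasma solubilities (α_cell = 3.38 × 10⁻⁵,
α_pl = 2.82 × 10⁻⁵) enter only as a small correction to the hemoglobin
term of the vessel balance; exit SO₂ moves by well under 1% when they are
varied ±20%.

Three quantities the parameter tables do not fix were set once, by
calibration against the zero-flux control and clearly-attributable
published responses, and never revisited:

* **Capillary radius R = 2.9 µm.** R sets the per-vessel O₂ carrying
  capacity πR²uC̃ and is therefore the dominant control on how far the
  network desaturates. Together with the layout choice below it puts the
  control venular-end SO₂ at 0.500 for the 16 µm-deep capillaries, 0.491
  at 33 µm, and 0.409 at 133 µm (targets ~50%/~40%).
* **Depth of the unlabeled middle double row (266/283 µm).** Only the
  depths 16/33/133 µm carry labels; placing the remaining 24 capillaries
  deeper spreads the supply over the consuming depth. With all rows
  crowded into the top 133 µm the deep labeled row would face the entire
  anoxic interior alone and end near 30% SO₂ regardless of other choices.
* **Arteriole velocity 4.35 × 10⁻² cm/s (3 × capillary).** Terminal
  arterioles carry faster flow; 3× reproduces the published arteriolar
  full-surface hypoxia response (−62% SO₂, +45% ATP) almost exactly. The
  faster transit also keeps the arteriole's ATP below its (radius-
  proportional) plateau.

The wall mass-transfer coefficient κ (default 2.5 × 10⁻⁵
ml O₂ cm⁻² s⁻¹ mmHg⁻¹) turns out to be *inert* over its plausible range
[1–6] × 10⁻⁵ in this geometry: exchange is demand-limited (the tissue
draws what consumption requires, and the blood equilibrates with clamped
tissue over the 532 µm length for any κ in that range). Exit SO₂ moved by
<0.3 percentage points over the whole bracket, so κ cannot serve as a
calibration dial here.

## Geometry and numbering

Capillaries are straight lines along y, hexagonally staggered in
"double rows": two sub-rows 17 µm apart, offset half a pitch in x
(12 per sub-row, 18 µm pitch). Numbering zigzags shallow/deep along x
within a double row. This scheme reproduces every published depth label
exactly — vessels 17 and 21 at 16 µm, 18 at 33 µm, 54 at 133 µm — and,
after the four lattice sites nearest the arteriole center are replaced
and the survivors renumbered, the variant labels too (14 at 33 µm, 17 at
16 µm, 50 at 133 µm, arteriole 69 at 30 µm). Exact cross-sectional
coordinates are not published; the layout is config-overridable
(`LayoutSpec`), and all quantitative comparisons attach to the labeled
vessels whose depths are fixed.

## Vessel–grid coupling

Each vessel segment owns a *wall map*: the wall circle is sampled at
fixed angles, each sample spread bilinearly onto the surrounding grid
columns, and the weights combined with exact axial overlaps so they sum
to the segment wall area 2πRΔy. The same weights scatter the wall flux
into the tissue and sample the wall PO₂, which makes the discrete
exchange conserve O₂ to round-off by construction.

A vessel thinner than the grid spacing is effectively a regularized line
source, and the sampled pressure lives at a discrete *effective radius*
r_eff rather than at the physical wall. r_eff is computed once per
(R, h) pair from a small 2D lattice Green's-function solve with the same
spreading stencil, and the spurious annulus between R and r_eff is folded
into the coupling coefficient (a Peaceman-type well index):

    κ_num = κ / (1 + κ R ln(r_eff/R) / (Dα)).

Without this correction the exchange strength would drift with grid
spacing; with it, venular-end SO₂ changes by <0.1% between h = 4 µm and
h = 2 µm on the reduced fixture.

Vessel lumen nodes are excluded from the consuming tissue volume but keep
a PO₂ value for stencil regularity (lumina are <1% of the volume).

## Steady-state solution

Two routes share one discrete fixed point:

* **Pseudo-time marching** — the literal time-dependent equations,
  explicit Euler with dt = safety·h²/(6·D_max) (D_max includes the
  facilitation ceiling), vessels stepped with the same dt, convergence
  declared when over a 1 s window max|ΔP| < 10⁻³ mmHg, max|ΔS| < 10⁻⁵,
  and monitored integrals (consumption, total ATP) change by < 10⁻⁴
  relative. Practical for the reduced fixtures; used to cross-check.
* **Accelerated elliptic solve** (default) — an outer Picard loop:
  (i) march every vessel's steady upwind balance segment-by-segment,
  solving each segment's scalar nonlinear equation by bisection so the
  fixed point matches the explicit scheme's exactly; (ii) freeze
  M(P)/(P+P_cr) (a positive linear sink — keeps the operator an M-matrix
  and the field non-negative, anoxic regions included), the facilitation
  coefficient, and the blood PO₂, and solve the symmetric positive-
  definite finite-volume system by preconditioned conjugate gradients.
  The preconditioner is an FFT (DCT-II) inverse of the constant-
  coefficient Neumann Laplacian plus the mean sink, so CG needs a few
  tens of iterations; warm starts make later outer iterations cheap.
  Two convergence accelerators matter: a symmetric rank-one-per-segment
  *blood compliance* term κwλ(P̄_w − P̄_w,frozen) with the local
  sensitivity λ = ∂P_b/∂P_w of the segment balance (same fixed point,
  removes the slow vessel–tissue feedback mode), and Anderson mixing
  (memory 4) on the outer iteration. Convergence criteria mirror the
  pseudo-time ones per outer pass.

On the 4-capillary fixture the two routes agree to |ΔS| < 6 × 10⁻⁴ at the
stated tolerances. Chamber conditions are Dirichlet values on the masked
z = 0 nodes, eliminated symmetrically from the linear system; all other
faces are mirror (zero-flux) planes. An empty clamp mask reproduces the
control bit-exactly.

## Problem sizes

The reference grid (h = 2 µm, 7.3M nodes) is supported but slow on one
core; production analyses and the acceptance script use h = 4 µm
(0.93M nodes), where a control solve takes ~2 minutes and warm-started
perturbed runs under a minute. Reduced fixtures (12-capillary "mini",
4-capillary "tiny") preserve the surface-vs-depth contrast and outlet
localization physics at ~1% of the cost and back the property tests.

## Derived metrics

Percent changes are relative to the zero-flux control,
100·(test − control)/control; SO₂ changes are additionally reported in
percentage points because narrative "dropped by X%" phrasing is ambiguous.
ATPtot is the lumen volume integral Σ A·πR²Δy in moles (it must grow with
the number of stimulated capillaries); ATPart is the same integral over
the arteriole, normalized against the control ATPtot. Penetration depths
are measured in the width-depth cross-section through the outlet center —
the plane the 3D profiles are sliced on — as the largest lateral (x)
distance from the outlet edge on the exposed face, and the largest depth
(z) above the outlet center, at which |P − P_control| exceeds a 1 mmHg
threshold (config-exposed and reported alongside the depths). Measured
anywhere else on the surface the metric would be dominated by the
perturbation that desaturated blood convects downstream (~240 µm for the
circle), which is a different physical statement.

## Validation oracles

* **Slab**: one clamped face, zero-order consumption limit; closed-form
  parabola, agreement to 0.06% of the clamp value at h = 2 µm.
* **Krogh–Erlang**: single centered capillary, myoglobin off. A square
  box cannot match an annulus at its edge (corner tissue adds ~27%
  consumption), so the oracle uses the equal-cross-sectional-area Krogh
  radius R_t = s/√π, under which the radial flux through any circle
  inside the inscribed region is exact for the *angle-averaged* profile;
  the comparison (r ∈ [10, 28] µm, mid-length) agrees to 1.5% of the
  profile drop.
* **ATP relaxation**: constant saturation gives
  A(y) = A∞(1 − e^(−y/λ)); the 50-segment upwind march matches to 1.4%
  of the plateau at segment midpoints.
* **Conservation**: at steady state total wall flux equals total
  consumption plus net chamber exchange to ~10⁻⁵ relative (audited
  explicitly, not assumed).

## What the reduced fixtures do not emulate

The fixtures keep straight, parallel, equal-velocity vessels, uniform
hematocrit and a single entrance saturation — like the full idealized
geometry, they contain no branching, no velocity heterogeneity, no
pulsatility, and no flow regulation feedback. Passing tests therefore
validate the transport solver and its discretization, not the idealized
geometry's fidelity to a real microvascular network.

## Known limitations

* The percent-change [ATP] responses are tied to the venular-end SO₂ by
  the release law: pct = 100·[(1 − C₁S_test)/(1 − C₁S_ctrl) − 1] whenever
  the exit lies several relaxation lengths downstream. Reported response
  pairs that do not satisfy this identity cannot be reproduced
  simultaneously by any implementation of these equations.
* With the tissue only 216 µm wide, the 200 µm square outlet and the
  clipped full-width rectangular slit differ by a ~8 µm margin strip, so
  their network-level effects are nearly degenerate in this geometry.
* Percent-change metrics are radius-invariant only at fixed saturation
  fields (the ATP equation is linear in R at the exit); through the O₂
  side, R changes the carrying capacity and hence the saturations — which
  is precisely why R could serve as the control calibration parameter.
* Intravascular radial gradients, discrete erythrocytes and plasma gaps
  are subsumed in κ; counter-current arrangements and reconstructed
  in-vivo networks are out of scope.
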