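# Methods

## Physical picture and scope

The package models the vertical component of a water strider's jump as a
surface-tension-dominated interaction between four synchronously rotating,
superhydrophobic thin legs and the free surface.  An order-of-magnitude
audit (`physics.force_scale_audit`) justifies the reduction: with the
measured exemplar scales for a medium strider (wetted length 7.5 mm, leg
radius 50 μm, body mass 30 mg, dimple growth rate 0.15 m s⁻¹, dimple depth
3 mm on water), dynamic pressure, buoyancy, added-mass and viscous forces
are 10⁻² to 10⁻⁵ of the capillary force, the body weight is 10⁻¹ of it, and
the detachment (wet-adhesion) energy loss is 10⁻⁴ of the takeoff kinetic
energy.  Orders are reported as floor(log₁₀·), which reproduces all printed
ratios with the exemplar inputs.  Horizontal propulsion physics (vortex
shedding, capillary waves), body-pitch rotation, per-leg asynchrony and
wetting dynamics are out of scope.

## Capillary force law

The upward force is taken as the weight of water displaced by the dimples.
For a thin cylinder pressed to depth h ≪ l_c, each of the two menisci
displaces a cross-section ≈ h·l_c, so per wetted length F′ = 2ρg l_c h =
2σh/l_c; over an effective wetted length C·l_w the total is

    F = 2 σ C l_w h / l_c.

This linear law is what makes the dimensionless mass index
M = m/(ρ l_c² C l_t) appear with no leftover constants, and it makes
M = 8·Ba an identity in the rigid limit with wetted perimeter P = 8 l_t (two
contact lines per leg, four legs).  The law overestimates the true
(saturating) restoring force as h approaches the quasi-static sinking depth
√2·l_c; we truncate it there by declaring meniscus rupture instead of
switching to the full nonlinear thin-cylinder solution.  The flexibility
factor C = (1 + 0.082 L_f^3.3)⁻¹, with L_f = l_w/l_ec and
l_ec = (B l_c/σ)^1/4 the elastocapillary length, discounts the wetted length
of a bending leg; the closed form is a fit valid for L_f < 2 and is
evaluated with a warning outside that range.  Young's modulus of leg cuticle
is not part of the measured exemplar set; the default is 10 GPa (typical
sclerotized cuticle) and all headline results use the rigid limit C = 1.

## Stroke model

The printed stroke formula is adopted in the bracket reading
l_s = y_i + (Δl/2)(1 − cos 2ωt), which satisfies the stated endpoint
conditions (l_s rises from the resting height y_i to the leg length l_l,
leg speed zero at both stroke ends with maximum ωΔl at mid-stroke) and
differentiates exactly to the leg-speed law v_s = ωΔl sin 2ωt; the literal
reading would start the stroke half-extended.  The leg angle θ is a derived
output used only for trace emulation, θ = arcsin of the fractional
extension, so it sweeps 0 → π/2 over the stroke and its time-averaged
derivative equals ω exactly on noiseless data.

## Jump dynamics

Combining the force law, momentum conservation (v = ∫F dt/m) and
h = l_s − y yields the piecewise dimensionless oscillator

    H″ = 2L cos 2τ − (2/(MΩ²)) W H          τ = ωt ∈ [0, π/2]

with W = 1 in the pushing stage and
W = [(π/2−τ)/(π/2−τ_m)]·(H/H_m) in the closing stage (wetted length
tapering with both phase and depth).  Initial conditions are H(0) = ε,
H′(0) = 0 with ε = 10⁻⁶ by default (a negligible pre-existing dimple);
results are insensitive to ε over [10⁻⁸, 10⁻⁴] (tested).  Stages and
terminal events:

* rupture: H = √2 rising → meniscus-breaking jump; the takeoff velocity is
  defined as V at the rupture instant (thrust assumed lost when the surface
  breaks), which produces the sharp performance collapse above the critical
  stroke rate;
* dimple maximum: first interior falling zero of H′ → (τ_m, H_m), switch to
  closing (this is also where the leg and body speeds cross, v_s = v);
* takeoff: H = 0 falling before τ = π/2 → post-takeoff closing;
* stroke end with H > 0: the legs stop, drive and capillary terms vanish,
  the body coasts and the relic dimple relaxes kinematically at
  H′ = −V/Ω until H = 0 (pre-takeoff closing), or never (no takeoff).

The body-weight term (+1/Ω² during the stroke, gravitational deceleration
during coasting) is excluded by default, consistent with the weight being an
order of magnitude below the capillary force and with the weight-free
momentum integral; the `include_weight` flag exists for sensitivity
analysis.  One consequence of the weightless default is worth stating: with
no static dimple, very slow strokes close their dimple mid-stroke and are
classified post-takeoff closing (with V_t → 0 linearly in Ω), so the
pre-takeoff regime appears as the band just below rupture at small L rather
than at small Ω.  The pushing stage with W = 1 is a driven linear
oscillator with spring constant k = 2/(MΩ²); its closed form — including
the resonant k = 4 case H = (L/2)τ sin 2τ with first maximum at
τ_m = 1.01438 (root of tan x = −x), H_m = 0.45493·L — serves as an
independent test oracle for the integrator, and the accumulated impulse is
carried as an extra state so that the identity V = Ω·∫(2WH/(MΩ²))dτ is
checked along every solution.

Integration uses `scipy.integrate.solve_ivp` with the stiff-capable LSODA
method, relative tolerance 10⁻⁸, absolute 10⁻¹⁰, a maximum step of 0.05 in
phase so no event is stepped over, and event-based stage switching; halving
the tolerance moves takeoff velocities by < 10⁻⁶ (tested).

## Optimization surfaces

`optimal.sweep_takeoff_map` simulates every cell of an (L, Ω) grid at fixed
M (defaults L ∈ [1, 7] × 61, Ω ∈ [0.2, 6] × 117, matching the ranges of the
published maps); per-cell solver failures are recorded, never fatal.  The
per-L optimum is the grid argmax refined by golden-section search between
the neighbouring grid points (derivative-free, since V_t(Ω) is kinked at
the rupture threshold); ties break toward smaller Ω, reading the animals'
observed safety margin below rupture as the tie-break.  The
meniscus-breaking threshold Ω_crit(L, M) is found by bisection to relative
10⁻⁴ (breaking is impossible for L ≤ √2, since even an unopposed stroke
only reaches depth ≈ L).  Because the stroke-phase dynamics depend on M and
Ω only through k = 2/(MΩ²), the product Ω_crit·M^1/2 collapses across M
essentially exactly, and V_t = √(2/M)·f(k, L): the mode of the optimal jump
depends on k alone, which makes the pre/post regime boundary L*
M-independent in this model (it is reported per-M regardless).  The
collapsed critical curve has the same 1/L fall-off as the reference line
Ω M^1/2 = 4/L + 0.1 drawn on the published phase diagram but sits at about
half its level; the comparison is reported as a correlation/shape check, not
asserted as an identity, since the exact printed force constant is not
recoverable from the available text.  With the default grids the boundary
computes to L* ≈ 3.35 at M = 0.5: optimal jumps for shorter reaches are
pre-takeoff closing, longer reaches post-takeoff closing, and in both cases
the optimal Ω sits within a fraction of a percent below Ω_crit for
L ≳ 2.6.  The optimum also minimizes the scaled escape time τ_t/Ω within
the post-takeoff band (the phase τ_t itself increases with Ω; it is the
physical time t_t = τ_t/ω that the fastest jump minimizes).

## Synthetic traces and what they do (not) show

`synthetic.generate_jump_trace` emulates the measurement pipeline of
500/1,000 frames-per-second video digitization: the simulated jump is
sampled at frame times, converted to physical units, and corrupted with
independent zero-mean Gaussian noise (standard deviation = `noise` × each
signal's range, default 2%) per frame and per leg replicate (two mid + two
hind legs), plus a constant per-leg offset (default `noise`/2) emulating
left/right asymmetry; leg velocity is the central finite difference of the
noisy leg distance, as a video pipeline would compute it.  Randomness uses
NumPy's PCG64 generator; every experiment records its child seeds, so any
single jump is regenerable in isolation.

Five species templates (small → large) provide uniform morphology ranges.
They are synthetic stand-ins, not measurements: the ranges bracket the two
printed exemplars (30 mg with 7.5 mm tibia+tarsus; 37.2 mg with 22.1 mm
legs), and each template's stroke-rate range was set once at 0.75–0.95 of
the rupture threshold of its mid-range morphology, mirroring the reported
behaviour of jumping a little below the critical line.  Consequently the
generator reproduces the *model's* kinematics with realistic sampling and
noise — it cannot validate the model against real animals, and passing
recovery tests demonstrate estimator correctness, not biological fidelity.
Real features it does not emulate: per-leg asynchrony statistics, body-pitch
rotation, digitization outliers, and trajectory inclination (all jumps are
perfectly vertical).

`synthetic.recover_parameters` averages the leg replicates, smooths with a
Savitzky–Golay filter (quartic, window scaled to the record length, ≤ 15
frames — a quadratic window attenuates the sinusoidal velocity peak by
several percent, a quartic by ≲ 0.2%), and reports three stroke-rate
estimates: the smoothed peak estimator v_s,max/Δl (primary), the raw
finite-difference peak estimator (upward-biased by noise — the maximum of a
noisy series — reported deliberately to expose that bias, median ≈ +19% at
2% noise), and the time-averaged angular-rate estimator.  Takeoff is
detected as the first raw zero crossing of the leg-averaged depth after the
dimple maximum (the depth drops steeply there, making the raw crossing
frame-accurate), with the body velocity at that frame from the smoothed
height derivative.  At 1,000 fps the noiseless round trip recovers ω to
≈ 0.2% and event times to within one frame; at 2% noise the median ω error
is ≈ 2%.

## Numerical and interface choices

* SI units everywhere internally; config files require explicit units
  ("30 mg", "7.5 mm") and reject bare numbers for dimensioned quantities, as
  well as unknown keys.
* Degenerate inputs raise typed errors: non-positive fluid constants,
  rest height outside (0, l_l), closing stage with a vanished dimple,
  non-monotonic time stamps, traces shorter than 10 frames.
* CLI exit codes: 0 success, 2 validation error, 3 solver failure in at
  least one sweep cell.
* Problem sizes used by the shipped reproduction script: the regime
  boundary uses a 117-point Ω grid bisected over L ∈ [2, 6] to ΔL = 0.02;
  recovery experiments default to 200 seeds at 1,000 fps.

## Known limitations

* The exact printed forms of the jump equations are not recoverable from
  the available text; the reconstruction is constrained by the printed
  dimensionless groups and validated against the printed consequences
  (regime boundary near L = 3.5, threshold collapse, optimum hugging the
  rupture line).  The absolute level of the critical curve differs from the
  published drawn line by a factor ≈ 2, consistent with an unknown O(1)
  constant in the force law; all mode topology and scaling conclusions are
  unaffected, but absolute Ω_crit values should be treated as model-relative.
* The linear force law is truncated, not saturated, at the sinking depth;
  near-rupture takeoff velocities are therefore slightly optimistic.
* Flight after takeoff ignores gravity unless `include_weight` is set, so
  post-takeoff trajectories are straight lines; only takeoff quantities
  should be read from them.
* The weight-on variant combines the closing-stage taper with an
  unsupported body weight and can classify very slow strokes as sinking
  (rupture with negative velocity); it is a sensitivity tool, not a resting
  model.
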