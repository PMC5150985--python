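# striderjump

Biomechanical modelling of how water striders jump vertically off the water
surface.

Water striders (Gerridae) escape predators attacking from below — fish,
backswimmers — with fast, near-vertical jumps.  Because the insect stands on
water, the jump is powered not by pushing against a solid substrate but by
pressing dimples into the free surface with its superhydrophobic middle and
hind legs: the restoring capillary force, equal to the weight of the water
displaced by the dimples, accelerates the body upward.  Push too gently and
little momentum is transferred; rotate the legs too fast and the dimples
exceed the quasi-static sinking depth of a thin cylinder, √2·l_c (≈3.8 mm on
water), the meniscus ruptures, and thrust is lost abruptly.  Jump
performance is therefore maximized by a morphology-specific leg-rotation
speed, and this package computes it.

`striderjump` is aimed at biomechanists and biomimetic-robot designers who
want a tested, scriptable implementation of the model: the dimensionless
jump dynamics, stroke-rate optimization maps, jump-mode phase diagrams, and
a synthetic generator that emulates high-speed-video jump traces for
estimator validation.

## The model

The legs rotate synchronously at constant angular velocity ω, sweeping the
stroke phase τ = ωt from 0 to π/2.  The leg-tip distance below the body
centre follows l_s = y_i + (Δl/2)(1 − cos 2ωt), so the downward leg speed is
v_s = ωΔl·sin 2ωt, with Δl = l_l − y_i the maximal reach.  Writing
H = h/l_c for the dimple depth in units of the capillary length
l_c = √(σ/ρg), the depth obeys a piecewise driven-oscillator equation over
the stroke phase:

    H″ = 2L cos 2τ − (2/(MΩ²)) · W · H

with dimensionless groups

* Ω = ω·√(l_c/g) — scaled leg-rotation rate (behaviour),
* M = m/(ρ l_c² C l_t) — body mass over the maximal mass of water the wetted
  tibia+tarsus (length l_t, flexibility factor C) can displace; M ≈ 8·Ba
  with the Baudoin number Ba = mg/(σP),
* L = Δl/l_c — scaled maximal leg reach (morphology),

and W the wetted-length taper: W = 1 while the legs push (up to the dimple
maximum at τ_m) and W = [(π/2−τ)/(π/2−τ_m)]·(H/H_m) while they close.  The
body velocity follows from momentum conservation, v = ∫F dt/m, equivalently
V = Ω(L sin 2τ − H′) with V = v/√(g l_c).  Each jump terminates as exactly
one of: **post-takeoff closing** (leg tips regain zero depth before the
stroke ends), **pre-takeoff closing** (stroke completes first, the body then
coasts free), **meniscus breaking** (H reaches √2; thrust assumed lost at
rupture), or **no takeoff**.

Sweeping (L, Ω) at fixed M maps the takeoff velocity V_t and classifies the
modes.  V_t grows with Ω up to the rupture threshold and collapses beyond
it, so long-legged striders (L ≳ 3.4) jump fastest by driving their legs
just below the meniscus-breaking condition, and the critical curve collapses
as Ω_crit·M^(1/2) ~ 1/L.

## Worked example

A medium-sized strider (body mass 30 mg, tibia+tarsus 7.5 mm, leg length
15 mm, resting height 6.45 mm) rotating its legs at ω = 52 rad s⁻¹ on water:

```python
import striderjump as sj

morph = sj.InsectMorphology(body_mass=30e-6, leg_length=15e-3,
                            support_length=7.5e-3, leg_radius=50e-6,
                            rest_height=6.45e-3)
groups = sj.dimensionless_groups(morph, sj.WATER, omega=52.0)
params = sj.JumpParameters(Omega=groups.Omega, mass_index=groups.mass_index,
                           reach=groups.reach)
res = sj.simulate_jump(params)
print(groups.Omega, groups.mass_index, groups.reach)
print(res.mode.value, res.H_m, res.V_t,
      sj.takeoff_velocity_physical(res, sj.WATER))
```

prints

```
Omega = 0.865, M = 0.544, L = 3.151
mode = post_takeoff_closing
H_m = 1.289 (h_m = 3.50 mm)
V_t = 3.727  ->  v_t = 0.608 m/s
escape time t_t = 29.7 ms
breaking threshold Omega_crit = 0.946
```

The dimple deepens to 3.5 mm — close to, but safely below, the 3.8 mm
rupture depth — the leg tips leave the surface before the stroke completes
(a post-takeoff closing jump), and the body takes off at 0.61 m s⁻¹ after
30 ms.  The chosen ω sits a little below the rupture threshold
(Ω_crit = 0.946), which is where the model puts the optimal stroke.

The same pipeline is scriptable from the shell:

```
striderjump audit --out out/            # capillary-dominance force audit
striderjump simulate --M 0.5 --Omega 0.7 --L 4 --out out/
striderjump sweep --M 0.1 --M 0.5 --M 2.0 --out out/   # Omega-L maps
striderjump synth --config run.yaml     # synthetic video traces
striderjump recover --config run.yaml   # estimator recovery experiment
```

## Layout

* `striderjump.physics` — fluid/insect constants, elastocapillary
  flexibility, dimensionless groups, force-scale audit
* `striderjump.kinematics` — sinusoidal stroke model and stroke-rate
  estimators
* `striderjump.dynamics` — the piecewise dimple ODE, event detection, mode
  classification
* `striderjump.optimal` — sweeps, optimal-Ω ridge, breaking threshold,
  regime boundary, phase diagram
* `striderjump.synthetic` — synthetic video-trace generator and
  parameter-recovery experiments
* `striderjump.config` / `striderjump.cli` — unit-checked configuration and
  the `striderjump` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
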