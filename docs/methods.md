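# Methods

This note documents the models behind `robogait`, the defaults and why they
were chosen, and what the synthetic generators do and do not emulate.

## Scope and assumptions

The package simulates the *algorithmic* layer of robot-assisted joint
testing: trajectory preparation, point-to-point execution with velocity
saturation, and fidelity scoring.  It deliberately models no rigid-body
dynamics, inertia, contact mechanics, robot kinematic chain or force-control
loop: the virtual robot positions the joint exactly along the passive path
and applies the axial force target exactly (plus optional noise).  These are
the right simplifications for studying discretization, velocity limits and
the statistics pipeline, which is what the package is for.

## Synthetic gait template (`gait`)

The template emulates averaged ovine gait dynamics over one cycle, in
percent-of-cycle g ∈ [0, 100):

- **Flexion**: two sin² lobes — a stance lobe of amplitude
  `stance_flexion_excursion` (default 7°) peaking mid-stance, and a swing
  lobe of amplitude `flexion_range` (default 30°) peaking mid-swing — on a
  baseline of `flexion_start` (default 50°, the heel-strike minimum).  Both
  lobes have zero value and slope at their phase boundaries, so the curve is
  C¹-periodic by construction.
- **Axial force**: a swing baseline `swing_load` (default 0.2 BW) plus two
  raised-cosine bumps peaking at 28% and 78% of stance; the second peak is
  85% of the first.  Peak value `axial_peak` (default 2.2 BW).  Stance
  occupies `stance_fraction` (default 54%) of the cycle.
- **Transverse references**: scaled copies of the axial curve with gains
  `pa_gain` = 0.25 and `ml_gain` = 0.12, giving in vivo-like magnitudes of a
  few tenths of a BW.

What it does *not* emulate: inter-stride variability, bimodal flexion during
stance, asymmetric swing, or measured transverse force shapes that are not
proportional to the axial load.  A passing pipeline therefore demonstrates
the algorithm's behavior on a representative smooth gait pattern, not
fidelity to any particular animal's data; users with their own curves can
load them from CSV and skip the template entirely.

## Junction correction

The filter family and cutoff are free choices; the implementation uses a
zero-phase (forward-backward) 2nd-order Butterworth applied to a triple
concatenation of the cycle, keeping the middle copy.  The cutoff is
expressed as a harmonic count of the gait cycle, default 10: low enough to
remove the wrap discontinuity's high-frequency content, high enough to leave
the double-peak stance load (≈2–3 harmonics) essentially untouched.  All
four channels are filtered identically so angle and force stay mutually
consistent.  One consequence worth knowing: the filter moves the cycle-start
angle and the swing peak by a few hundredths of a degree, so the topmost
passive-path pose may never be commanded even though the recording spans the
full nominal range.

## Trajectory preparation

- Angle levels are anchored at the cycle-start angle.  Absolute anchoring
  (multiples of the increment) would shift every point by less than one
  increment; nothing downstream distinguishes the two, since the loaded-path
  construction maps each angle to the nearest passive-path pose anyway.
- The velocity "differential" is taken with respect to gait percent, not
  sample index: on a fixed-increment discretization an index differential is
  constant and could not produce a smoothly varying profile.  The circular
  predecessor (last point before first) closes the cycle without shortening
  the vector.
- The midpoint rule keeps the shared level angle rather than the true
  extremum angle; this keeps every commanded angle on the passive-path grid.
- Force between points is held stepwise at the destination point's target,
  matching superimposed control where each waypoint carries its force
  setpoint.  Where only two points span a fast force change, this step
  dominates the axial residual error — visible as the elevated ε_k bins at
  the end of stance in the default run.

## Passive path and rotation center

`generate_passive_path` produces poses that rotate the femur frame about a
fixed axis through a configurable center, plus seeded isotropic Gaussian
translational noise (default in the pipeline: 0.05 mm, the order of a good
industrial robot's pose reproducibility).  Real passive flexion is not
single-axis — the knee's instantaneous axis migrates — so the generator
validates the estimator and the pipeline plumbing, not anatomical realism.

The minimal-amplitude point solves the normal equations of
min_p Σ_t ‖(R_t − R̄)p + (d_t − d̄)‖².  For single-axis motion the normal
matrix is rank-2: the solution is only defined up to translation along the
axis, and the pseudo-inverse (relative tolerance 1e-8) selects the
minimum-norm representative along the null direction.  Callers get a
conditioning diagnostic (ratio of the two largest eigenvalues) and a
`residual_amplitude` (RMS of the center's base-frame trajectory about its
mean).  Motion spanning less than 5° of rotation (configurable) is rejected
as degenerate rather than returning an unstable estimate.  No acceptance
threshold on the recentered axis is imposed; the residual amplitude is
exposed for the user to judge.

## Virtual robot

Per segment the executed speed is `min(v_cmd, v_cap, Δθ / t_min)`:

- `v_cap` = 10 °/s, a typical occupational-safety limit for fenceless
  operation.
- `t_min` = 0.05 s per waypoint (two 24 ms controller ticks).  This single
  latency parameter reproduces the qualitative optimal-increment pattern —
  at a 10 °/s target, increments of 0.5° and above reach the target while
  0.4° and below fall short (8, 6, 4, 2 °/s for 0.4, 0.3, 0.2, 0.1°) — but a
  single parameter cannot simultaneously match every reported slowdown of a
  physical controller (real controllers show a softer roll-off at very fine
  increments).  `t_min` is therefore configurable.
- Gait percent within a trace is assigned from the commanded schedule
  (elapsed fraction of each segment), not by inverting the angle, so capped
  executions still bin correctly and the executed-vs-commanded timing lag
  isolates the cap's effect: zero until the first capped segment (always in
  swing for 15–20 °/s commands), growing monotonically afterwards.
- Traces are sampled at 24 ms.  `max_achieved_velocity` smooths the sampled
  finite differences with a centered 3-sample moving average before taking
  the maximum, suppressing aliasing at segment boundaries.  The exact
  per-cycle period is carried on the trace (`cycle_period`) because a 24 ms
  sampling grid quantizes period estimates too coarsely for tight scaling
  checks.

## Virtual joint

Transverse forces are synthesized as backlash:
`F = gain · F_axial[BW] · (1 + amp · sin(π(θ − θ₀)/span + φ))`, with
per-cycle multiplicative gain jitter and per-sample additive noise, all
seeded.  Defaults were chosen analytically so the default pipeline lands in
the dispersion and error ranges a physical experiment of this kind reports
(σ_total of order 0.03 / 0.12 / 0.20 BW for axial / PA / ML; largest
ε_total for PA):

- `pa_gain` = −0.35 (sign-flipped relative to the 0.25 reference gain:
  without active muscle pull the passive structures react opposite to the in
  vivo anterior force — this is what makes PA the least faithful channel),
  shape amplitude 0.5;
- `ml_gain` = 0.16 vs the 0.12 reference, shape amplitude 0.4, phase 1.5;
- per-sample noise SDs 0.08 / 0.35 / 0.60 BW (axial / PA / ML) — bin
  averaging over ~8 samples per cell reduces these by ≈√8;
- per-cycle gain jitter SD 0.10 (not reduced by within-cycle averaging).

The joint model's only contract is to produce transverse curves of in
vivo-like form with larger dispersion than the controlled axial channel; it
encodes no ligament or meniscus mechanics.

## Metrics

ε_k aggregates squared deviations over specimens and cycles (RMS), ε_total
RMS-aggregates over the 100 bins; σ_k is the sample SD (ddof = 1) over the
m·n cells of a bin, σ_total the RMS over bins.  The SD convention is
switchable (`ddof=0` for the population form); the difference is below 1%
for the default 560 cells per bin.  The reference is interpolated at bin
*centers* (k + 0.5%), consistent with comparing against bin means; for
smooth curves the difference from edge interpolation is second order.
Binning uses half-open intervals [k, k+1) and errors loudly on any empty
(bin, cycle) cell rather than imputing.

## Problem sizes and determinism

The default pipeline runs 4 specimens × 200 cycles (60 preconditioning) at a
0.5° increment and 24 ms sampling — about 3.4 million samples, a few seconds
of compute.  Unit tests use scaled-down runs (1 specimen, ≤ 8 cycles) that
exercise every stage; the acceptance script runs the full default sizes.
All randomness flows through explicit integer seeds; per-specimen and
per-replicate streams are derived from the base seed with fixed multipliers,
so identical configurations reproduce byte-identical artifacts.

## Known limitations

- Single-axis passive paths; no instantaneous-axis migration.
- Ideal position and force control; no servo dynamics or force overshoot.
- The latency model is a hard per-waypoint floor, not a controller model;
  match `t_min` to your hardware before reading physical meaning into the
  optimal increment.
- The transverse-force model is phenomenological; its defaults target
  realistic dispersion magnitudes, not any specific joint's mechanics.
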