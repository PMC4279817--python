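# robogait

Simulation of robot-assisted reproduction of in vivo joint dynamics.

Robotic joint testing rigs replay a specimen's *passive flexion path* — the
sequence of femur-in-tibia poses recorded while the joint is flexed along its
path of minimal resistance — under superimposed force/torque control, so that
in vivo gait dynamics (flexion angle and axial contact force over a
heel-strike-to-heel-strike cycle) can be imposed on a knee specimen in vitro.
`robogait` implements that workflow end to end as an in-silico simulator, for
biomechanics researchers who want to study, tune or teach the algorithm
without a robot: discretization of the gait curve onto the passive-path angle
grid, velocity-saturated execution on a virtual robot against a virtual
joint, and the fidelity statistics used to judge the reproduction.

## The algorithm

Given a gait curve θ(g), F(g) on a percent-of-cycle grid g ∈ [0, 100):

1. **Junction correction** — three copies of the cycle are concatenated,
   low-pass filtered with a zero-phase 2nd-order Butterworth (cutoff given as
   a harmonic count of the cycle), and the middle copy kept, removing the
   pulse at the 100% → 0% wrap.
2. **Incremental interpolation** — trajectory points are placed where θ(g)
   crosses angle levels spaced by the increment Δθ (e.g. 0.5°), by linear
   inverse interpolation within each monotone stretch; a 30° monotone span at
   0.5° gives an initial point plus 60 crossings, 61 points.  Adjacent
   equal-angle points at local extrema merge into their gait-percent midpoint
   (the *midpoint rule*), so no segment commands zero velocity.
3. **Velocity profile** — the commanded speed at point *i* is
   w_i = |θ_i − θ_{i−1}| / Δg_i with circular predecessor, normalized to unit
   maximum and scaled to the desired peak v_max; the axial force command is
   F(g) interpolated at each point, in body-weight (BW) units, multiplied by
   the specimen's body weight in N.
4. **Execution** — each segment runs at min(v_cmd, v_cap, Δθ/t_min): a 10 °/s
   safety cap and a per-waypoint controller latency t_min that throttles
   densely spaced points (which is why the *optimal increment* is the
   smallest one still reaching the target speed).  The axial force is held
   stepwise between points; transverse (posterior-anterior, medio-lateral)
   forces emerge from a virtual joint as backlash.  The rotation center of
   the passive path is estimated as the *minimal amplitude point* — the
   least-squares minimizer p of Σ_t ‖(R_t − R̄)p + (d_t − d̄)‖² — and the
   path recentered on it.
5. **Metrics** — forces of the analyzed cycles (after discarding
   preconditioning cycles) are averaged into 1%-of-cycle bins, giving cells
   F_kij (bin k, specimen i, cycle j) in BW, and compared to the reference
   F_k,ref interpolated at each percent:

       ε_k = √( 1/(mn) Σ_ij (F_kij − F_k,ref)² ),   ε_total = √( 1/p Σ_k ε_k² )
       σ_k = SD over the mn cells of bin k,          σ_total = √( 1/p Σ_k σ_k² )

   with p = 100 bins.

Published averaged ovine gait data are not redistributable, so the package
ships a parametric synthetic template (flexion 50–80°, stance 0–54% of cycle
with ≈7° excursion, double-peak axial stance load, near-unloaded swing) and a
synthetic rigid-motion generator standing in for robot-recorded passive
flexion; both are seeded and deterministic.

## Worked example

```
$ python examples/05_full_pipeline.py
trajectory points per cycle: 144
cycle period: 20.44 s
rotation-center recovery error per specimen [mm]: ['0.038', '0.028', '0.021', '0.068']

component   eps_total [BW]   sd_total [BW]
axial                0.207           0.028
pa                   0.648           0.127
ml                   0.229           0.207
```

Four virtual specimens (body weights 300/300/300/350 N) each execute 200 gait
cycles at a 0.5° increment and 10 °/s peak velocity; the first 60 cycles are
preconditioning and excluded from analysis.  The actively controlled axial
force is reproduced most faithfully — smallest residual error ε_total and
smallest cycle-to-cycle scatter σ_total — while the uncontrolled transverse
components show larger dispersion, and the posterior-anterior channel the
largest residual error (passive structures cannot substitute for muscle
action).  The other examples (`examples/01_…` to `04_…`) walk through the
template, the discretization, rotation-center estimation and the velocity
limits individually.

A thin CLI wraps the same functions
(`robogait run-all --seed 1 --out runs/demo`, plus `generate-gait`,
`record-passive`, `prepare-trajectory`, `find-increment`, `simulate`,
`metrics`); every run writes a manifest that makes it byte-for-byte
reproducible.

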