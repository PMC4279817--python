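"""Virtual execution of a loaded flexion path.

The robot replays points of the passive flexion path under superimposed
force/torque control: flexion angle is position-controlled point to point
while the axial force is regulated to the trajectory's target, held stepwise
between points.  Two effects limit the achieved angular speed:

* a safety cap ``v_cap`` (10 deg/s by default) on the commanded velocity, and
* a per-waypoint controller latency ``t_min``: points closer together than
  ``v * t_min`` cannot be traversed faster than ``increment / t_min``, which
  is what makes very fine increments slow in practice and motivates choosing
  the smallest increment that still reaches the desired peak velocity.

Per segment the executed velocity is ``min(v_cmd, v_cap, dtheta / t_min)``
and the angle is linear in time within the segment.  Transverse
(posterior-anterior and medio-lateral) forces are not controlled; a virtual
joint model synthesizes them as a backlash response proportional to the axial
load with a smooth angle-dependent modulation, per-cycle gain jitter and
additive noise.  The trace is sampled at a fixed period (24 ms by default)
over many cycles.

Gait percent within the trace is assigned from the commanded schedule
(elapsed fraction of each segment), so velocity-capped executions still bin
correctly for the fidelity metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DegeneratePathError,
    ParameterError,
    RangeError,
    RuntimeFailure,
)
from .gait import GaitCurve
from .kinematics import PassivePath, generate_passive_path
from .trajectory import Trajectory, build_trajectory

__all__ = [
    "RobotParams",
    "JointModelParams",
    "LoadedPath",
    "RobotTrace",
    "build_loaded_path",
    "simulate_execution",
    "max_achieved_velocity",
    "find_optimal_increment",
]


@dataclass(frozen=True)
class RobotParams:
    """Virtual robot controller parameters.

    v_cap : safety limit on flexion speed [deg/s].
    t_min : per-waypoint controller latency [s]; a segment can never take
        less than ``t_min``.  Default 0.05 s (two 24 ms controller ticks),
        which reproduces the observed velocity reduction for increments of
        0.4 deg and below at a 10 deg/s target.
    sample_dt : trace sampling period [s].
    n_cycles / n_precondition : total simulated gait cycles and the initial
        preconditioning cycles discarded from analysis.
    """

    v_cap: float = 10.0
    t_min: float = 0.05
    sample_dt: float = 0.024
    n_cycles: int = 200
    n_precondition: int = 60

    def __post_init__(self) -> None:
        if self.v_cap <= 0:
            raise ParameterError("v_cap: must be > 0")
        if self.t_min < 0:
            raise ParameterError("t_min: must be >= 0")
        if self.sample_dt <= 0:
            raise ParameterError("sample_dt: must be > 0")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles: must be >= 1")
        if not 0 <= self.n_precondition < self.n_cycles:
            raise ParameterError("n_precondition: must be in [0, n_cycles)")


@dataclass(frozen=True)
class JointModelParams:
    """Virtual joint producing backlash forces from the axial load.

    The transverse response is ``gain * f_axial[BW] * shape(angle)`` with
    ``shape(angle) = 1 + amp * sin(pi * (angle - start) / span + phase)``,
    per-cycle multiplicative gain jitter, and additive per-sample noise.
    Gains are BW of transverse force per BW of axial load; noise SDs are in
    BW.  The default PA gain is negative (posteriorly directed): without
    active muscle pull the passive structures react opposite to the in vivo
    anterior force, which is what makes the PA channel the least faithful.
    """

    pa_gain: float = -0.35
    ml_gain: float = 0.16
    pa_shape: tuple[float, float] = (0.5, 0.0)
    ml_shape: tuple[float, float] = (0.4, 1.5)
    noise_sd_axial: float = 0.08
    noise_sd_pa: float = 0.35
    noise_sd_ml: float = 0.60
    cycle_jitter_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd_axial", "noise_sd_pa", "noise_sd_ml"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name}: must be >= 0")
        if self.cycle_jitter_sd < 0:
            raise ParameterError("cycle_jitter_sd: must be >= 0")


@dataclass(frozen=True)
class LoadedPath:
    """Loaded flexion path: passive-path indices with dynamics per point.

    path_index : index of each trajectory point on the passive path.
    velocity : commanded speed [deg/s] of the segment ending at the point.
    axial_force : target axial force [N] at the point.
    gait_pct : commanded gait schedule [%] of each point.
    body_weight : body weight [N] used for the force conversion.
    """

    path_index: np.ndarray
    velocity: np.ndarray
    axial_force: np.ndarray
    gait_pct: np.ndarray
    body_weight: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.path_index, int)
        object.__setattr__(self, "path_index", idx)
        for name in ("velocity", "axial_force", "gait_pct"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = len(idx)
        if not (
            len(self.velocity) == len(self.axial_force) == len(self.gait_pct) == n
        ):
            raise ParameterError("loaded path vectors must have identical length")
        if n < 2:
            raise ParameterError("loaded path: need at least 2 points")
        if np.any(self.velocity <= 0):
            raise ParameterError("velocity: must be > 0")

    @property
    def n(self) -> int:
        return len(self.path_index)


@dataclass(frozen=True)
class RobotTrace:
    """Time-sampled record of an executed simulation.

    Arrays share one length: time [s] on a uniform ``sample_dt`` grid, cycle
    index, gait percent from the commanded schedule, flexion angle [deg] and
    the three measured force components [N].  ``cycle_period`` is the exact
    per-cycle duration [s] of the executed schedule.
    """

    time: np.ndarray
    cycle: np.ndarray
    gait_pct: np.ndarray
    angle: np.ndarray
    f_axial: np.ndarray
    f_pa: np.ndarray
    f_ml: np.ndarray
    sample_dt: float
    cycle_period: float

    @property
    def n(self) -> int:
        return len(self.time)

    def force(self, component: str) -> np.ndarray:
        try:
            return {"axial": self.f_axial, "pa": self.f_pa, "ml": self.f_ml}[
                component
            ]
        except KeyError:
            raise ParameterError(f"component: unknown force component {component!r}")


def build_loaded_path(
    traj: Trajectory, path: PassivePath, body_weight: float
) -> LoadedPath:
    """Map trajectory angles onto passive-path indices and scale forces to N.

    Each trajectory angle is substituted by the index of the nearest passive
    path point, ``round((angle - start_angle) / increment)`` with round-half-
    to-even; angles must not deviate from the path grid by more than half an
    increment and must stay within the recorded span.
    """
    if abs(traj.increment - path.increment) > 1e-9:
        raise ParameterError(
            f"increment: trajectory ({traj.increment}) and passive path "
            f"({path.increment}) disagree"
        )
    if body_weight <= 0:
        raise ParameterError("body_weight: must be > 0")
    rel = (traj.angle - path.start_angle) / path.increment
    idx = np.rint(rel).astype(int)  # round-half-to-even
    off_grid = np.abs(rel - idx) > 0.5 + 1e-9
    if np.any(off_grid):
        raise RangeError(
            f"angle {traj.angle[np.argmax(off_grid)]:.4f} deg deviates from the "
            "passive-path grid by more than half an increment"
        )
    if idx.min() < 0 or idx.max() >= path.n:
        bad = traj.angle[np.argmax((idx < 0) | (idx >= path.n))]
        raise RangeError(
            f"angle {bad:.4f} deg outside passive-path span "
            f"[{path.start_angle:g}, {path.start_angle + path.span:g}] deg"
        )
    return LoadedPath(
        path_index=idx,
        velocity=traj.velocity.copy(),
        axial_force=traj.axial_force * body_weight,
        gait_pct=traj.gait_pct.copy(),
        body_weight=float(body_weight),
    )


def _segment_schedule(loaded: LoadedPath, path: PassivePath, robot: RobotParams):
    """Per-cycle node schedule.

    Returns node arrays over one cycle: executed arrival times, commanded
    (uncapped) arrival times, angles, unwrapped gait percents and held axial
    forces.  Node 0 is the cycle-start point; the final node is the same
    point one cycle later (wrap segment included).
    """
    angles = path.start_angle + path.increment * loaded.path_index.astype(float)
    # segment ending at point i starts at point i-1 (circular)
    dtheta = np.abs(angles - np.roll(angles, 1))
    if np.any(dtheta <= 0):
        raise DegeneratePathError(
            "zero-length segment: consecutive points share a passive-path index"
        )
    v_cmd = np.minimum(loaded.velocity, robot.v_cap)
    if robot.t_min > 0:
        v_exec = np.minimum(v_cmd, dtheta / robot.t_min)
    else:
        v_exec = v_cmd
    dur_exec = dtheta / v_exec
    dur_cmd = dtheta / loaded.velocity  # uncapped commanded durations
    dg = np.mod(loaded.gait_pct - np.roll(loaded.gait_pct, 1), 100.0)

    # cycle starts at point 0; traverse segments 1..n-1, then the wrap
    # segment (index 0) back to point 0 of the next cycle
    order = np.r_[np.arange(1, loaded.n), 0]
    t_exec = np.r_[0.0, np.cumsum(dur_exec[order])]
    t_cmd = np.r_[0.0, np.cumsum(dur_cmd[order])]
    node_angle = np.r_[angles[0], angles[order]]
    node_g = np.r_[0.0, np.cumsum(dg[order])] + loaded.gait_pct[0]
    node_force = np.r_[loaded.axial_force[0], loaded.axial_force[order]]
    return t_exec, t_cmd, node_angle, node_g, node_force


def simulate_execution(
    loaded: LoadedPath,
    path: PassivePath,
    robot: RobotParams,
    joint: JointModelParams,
) -> RobotTrace:
    """Execute a loaded path for ``robot.n_cycles`` cycles and sample a trace.

    Deterministic for identical inputs and ``joint.seed``.
    """
    t_exec, _, node_angle, node_g, node_force = _segment_schedule(
        loaded, path, robot
    )
    period = float(t_exec[-1])
    total = period * robot.n_cycles
    n_samples = int(np.floor(total / robot.sample_dt)) + 1
    t = np.arange(n_samples) * robot.sample_dt
    cycle = np.minimum((t / period).astype(int), robot.n_cycles - 1)
    tau = t - cycle * period

    angle = np.interp(tau, t_exec, node_angle)
    g = np.mod(np.interp(tau, t_exec, node_g), 100.0)
    # force held stepwise at the destination point of the running segment
    seg = np.clip(np.searchsorted(t_exec, tau, side="left"), 1, len(t_exec) - 1)
    f_ax_target = node_force[seg]

    rng = np.random.default_rng(joint.seed)
    jit_pa = 1.0 + rng.normal(0.0, joint.cycle_jitter_sd, robot.n_cycles)
    jit_ml = 1.0 + rng.normal(0.0, joint.cycle_jitter_sd, robot.n_cycles)
    bw = loaded.body_weight
    ax_bw = f_ax_target / bw

    span = max(path.span, 1e-12)
    phase = np.pi * (angle - path.start_angle) / span
    amp_pa, phi_pa = joint.pa_shape
    amp_ml, phi_ml = joint.ml_shape
    shape_pa = 1.0 + amp_pa * np.sin(phase + phi_pa)
    shape_ml = 1.0 + amp_ml * np.sin(phase + phi_ml)

    f_axial = f_ax_target + rng.normal(0.0, joint.noise_sd_axial * bw, n_samples)
    f_pa = (
        joint.pa_gain * jit_pa[cycle] * ax_bw * shape_pa
        + rng.normal(0.0, joint.noise_sd_pa, n_samples)
    ) * bw
    f_ml = (
        joint.ml_gain * jit_ml[cycle] * ax_bw * shape_ml
        + rng.normal(0.0, joint.noise_sd_ml, n_samples)
    ) * bw

    return RobotTrace(
        time=t,
        cycle=cycle,
        gait_pct=g,
        angle=angle,
        f_axial=f_axial,
        f_pa=f_pa,
        f_ml=f_ml,
        sample_dt=robot.sample_dt,
        cycle_period=period,
    )


def max_achieved_velocity(trace: RobotTrace) -> float:
    """Peak flexion speed [deg/s] measured from a sampled trace.

    Finite differences of the sampled angle divided by the sampling period,
    smoothed with a centered 3-sample moving average to suppress aliasing at
    segment boundaries, then maximized.
    """
    if trace.n < 2:
        raise ParameterError("trace: need at least 2 samples")
    v = np.abs(np.diff(trace.angle)) / trace.sample_dt
    if len(v) >= 3:
        v = np.convolve(v, np.ones(3) / 3.0, mode="valid")
    return float(v.max())


def find_optimal_increment(
    curve: GaitCurve,
    candidates,
    v_target: float,
    robot: RobotParams,
    tol: float = 0.02,
) -> float:
    """Smallest increment whose simulated execution reaches the target speed.

    For each candidate increment (ascending) the gait curve is discretized,
    executed for one cycle on an ideal noise-free passive path, and the max
    achieved velocity measured from the sampled trace; the first candidate
    reaching ``v_target * (1 - tol)`` wins.  Finer increments give smoother
    force profiles, so the smallest workable one is preferred.
    """
    candidates = sorted(float(c) for c in candidates)
    if not candidates:
        raise ParameterError("candidates: must be non-empty")
    if v_target <= 0:
        raise ParameterError("v_target: must be > 0")
    one_cycle = replace(robot, n_cycles=1, n_precondition=0)
    best = (None, -np.inf)
    for inc in candidates:
        traj = build_trajectory(curve, inc, v_target)
        anchor = float(curve.flexion[0])
        k = np.rint((traj.angle - anchor) / inc).astype(int)
        start = anchor + k.min() * inc
        span = (k.max() - k.min()) * inc
        ideal = generate_passive_path(
            center=np.zeros(3),
            axis=np.array([1.0, 0.0, 0.0]),
            start_angle=start,
            increment=inc,
            span=span,
        )
        loaded = build_loaded_path(traj, ideal, body_weight=300.0)
        trace = simulate_execution(
            loaded, ideal, one_cycle, JointModelParams(seed=0)
        )
        v = max_achieved_velocity(trace)
        if v > best[1]:
            best = (inc, v)
        if v >= v_target * (1.0 - tol):
            return inc
    raise RuntimeFailure(
        f"no candidate reached {v_target:g} deg/s; best was increment "
        f"{best[0]:g} deg at {best[1]:.3g} deg/s"
    )
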