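"""Conversion of a gait curve into a robot-executable trajectory.

A robot that replays a passive flexion path can only stop at path points,
which sit at fixed flexion-angle increments.  The gait curve (angle vs percent
of cycle) is therefore discretized by *incremental interpolation*: within each
monotone stretch of the flexion curve, points are placed where the curve
crosses angle levels spaced by the increment and anchored at the cycle-start
angle, with the gait percent of each crossing obtained by linear inverse
interpolation.  Where the curve turns around exactly between two levels, the
two adjacent equal-angle points would command zero angular velocity; the
*midpoint rule* replaces each such pair by a single point at the mean gait
percent.

The commanded angular velocity at each point is the absolute differential of
the angle with respect to gait percent, computed circularly (the predecessor
of the first point is the last point), normalized to unit maximum and scaled
to the desired peak velocity.  The axial force command is the gait curve's
axial channel linearly interpolated (with wrap-around) at each point's gait
percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegeneratePathError, ParameterError
from .gait import GaitCurve

__all__ = [
    "Trajectory",
    "interpolate_increments",
    "apply_midpoint_rule",
    "velocity_profile",
    "interpolate_force",
    "scale_to_body_weight",
    "build_trajectory",
]

_ANGLE_TOL = 1e-9


@dataclass(frozen=True)
class Trajectory:
    """One robot gait cycle: equal-length point vectors plus metadata.

    Attributes
    ----------
    gait_pct : ndarray
        Percent-of-cycle of each point, in [0, 100), increasing.
    angle : ndarray
        Flexion angle [deg]; adjacent entries always differ.
    velocity : ndarray
        Commanded angular speed [deg/s] for the segment *ending* at each
        point (circular: the first point's segment starts at the last point).
    axial_force : ndarray
        Target axial force [BW] at each point.
    increment : float
        Angle spacing [deg] used for the interpolation.
    v_max : float
        Peak commanded velocity [deg/s]; ``max(velocity) == v_max``.
    """

    gait_pct: np.ndarray
    angle: np.ndarray
    velocity: np.ndarray
    axial_force: np.ndarray
    increment: float
    v_max: float

    def __post_init__(self) -> None:
        for name in ("gait_pct", "angle", "velocity", "axial_force"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = len(self.gait_pct)
        if not (len(self.angle) == len(self.velocity) == len(self.axial_force) == n):
            raise ParameterError("trajectory vectors must have identical length")
        if n < 2:
            raise ParameterError("trajectory: need at least 2 points")
        if np.any(np.diff(self.gait_pct) <= 0):
            raise ParameterError("gait_pct: must be strictly increasing")
        if self.gait_pct[0] < 0 or self.gait_pct[-1] >= 100:
            raise ParameterError("gait_pct: must lie in [0, 100)")
        if np.any(np.abs(np.diff(self.angle)) <= _ANGLE_TOL):
            raise ParameterError("angle: adjacent points must not share an angle")
        if np.any(self.velocity <= 0):
            raise ParameterError("velocity: must be > 0 everywhere")
        if abs(self.velocity.max() - self.v_max) > 1e-9 * max(self.v_max, 1.0):
            raise ParameterError("velocity: maximum must equal v_max")

    @property
    def n(self) -> int:
        return len(self.gait_pct)


def interpolate_increments(
    curve: GaitCurve, increment: float
) -> tuple[np.ndarray, np.ndarray]:
    """Place trajectory points at fixed angle increments along the gait curve.

    The sampled flexion curve is treated as piecewise linear in gait percent.
    Angle levels are anchored at the cycle-start angle ``flexion[0]`` and
    spaced by ``increment``.  The first output point is the cycle start
    itself; every subsequent point is a level crossing, emitted in traversal
    order.  A sample that lies exactly on a level is emitted once.  The curve
    is traversed open (first to last grid point); the wrap back to the start
    is handled downstream by the circular velocity profile.

    Returns
    -------
    (gait_pct, angle) : pair of ndarray
        Crossing positions and their angles, traversal-ordered.  Adjacent
        equal-angle pairs at extrema are *not* merged here; apply
        :func:`apply_midpoint_rule` next.
    """
    flexion_range = float(np.ptp(curve.flexion))
    if increment <= 0:
        raise ParameterError("increment: must be > 0")
    if flexion_range > 0 and increment >= flexion_range:
        raise ParameterError(
            f"increment: {increment} deg is not below the flexion range "
            f"{flexion_range:g} deg"
        )
    g = curve.grid
    theta = curve.flexion
    anchor = float(theta[0])
    tol = _ANGLE_TOL * max(1.0, abs(anchor))

    out_g = [float(g[0])]
    out_a = [anchor]
    for i in range(len(g) - 1):
        ga, gb = g[i], g[i + 1]
        ta, tb = theta[i], theta[i + 1]
        if tb > ta + tol:  # ascending interval: levels in (ta, tb]
            k_lo = int(np.ceil((ta - anchor) / increment - 1e-9))
            if anchor + k_lo * increment <= ta + tol:
                k_lo += 1
            k_hi = int(np.floor((tb - anchor) / increment + 1e-9))
            ks = range(k_lo, k_hi + 1)
        elif tb < ta - tol:  # descending interval: levels in [tb, ta)
            k_hi = int(np.floor((ta - anchor) / increment + 1e-9))
            if anchor + k_hi * increment >= ta - tol:
                k_hi -= 1
            k_lo = int(np.ceil((tb - anchor) / increment - 1e-9))
            ks = range(k_hi, k_lo - 1, -1)
        else:
            continue  # flat interval: no crossings
        for k in ks:
            level = anchor + k * increment
            frac = (level - ta) / (tb - ta)
            out_g.append(float(ga + frac * (gb - ga)))
            out_a.append(float(level))
    return np.asarray(out_g), np.asarray(out_a)


def apply_midpoint_rule(
    points: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent equal-angle points into their gait-percent midpoint.

    At a local extremum that falls between two angle levels, incremental
    interpolation emits the same level twice in a row, which would command
    zero angular velocity between the two points.  Each adjacent equal-angle
    pair is replaced by one point at the mean of the two gait percents with
    the shared angle, repeatedly, until no adjacency remains.  Non-extremal
    points are untouched; the call is the identity on clean input.
    """
    g = list(np.asarray(points[0], float))
    a = list(np.asarray(points[1], float))
    if len(g) != len(a):
        raise ParameterError("points: gait_pct and angle lengths differ")
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(a) - 1:
            if abs(a[i + 1] - a[i]) <= _ANGLE_TOL:
                g[i] = 0.5 * (g[i] + g[i + 1])
                del g[i + 1], a[i + 1]
                changed = True
            else:
                i += 1
    return np.asarray(g), np.asarray(a)


def velocity_profile(
    points: tuple[np.ndarray, np.ndarray], v_max: float
) -> np.ndarray:
    """Commanded angular speed per point from the circular angle differential.

    The raw speed associated with point *i* is ``|theta_i - theta_{i-1}| /
    dg_i`` where the predecessor of the first point is the *last* point and
    gait-percent differences are taken modulo 100 (the cycle is closed by
    prepending the end value, so the profile length equals the point count).
    The raw profile is normalized to unit maximum and scaled by ``v_max``, so
    the returned maximum equals ``v_max`` exactly.
    """
    g = np.asarray(points[0], float)
    a = np.asarray(points[1], float)
    if len(g) < 2:
        raise ParameterError("points: need at least 2 points")
    if v_max <= 0:
        raise ParameterError("v_max: must be > 0")
    dg = np.mod(g - np.roll(g, 1), 100.0)
    if np.any(dg == 0):
        raise DegeneratePathError(
            "degenerate spacing: two points share the same gait percent"
        )
    dtheta = np.abs(a - np.roll(a, 1))
    w = dtheta / dg
    w_max = w.max()
    if w_max <= 0:
        raise DegeneratePathError("degenerate profile: no angular motion")
    return v_max * (w / w_max)


def interpolate_force(curve: GaitCurve, gait_pcts: np.ndarray) -> np.ndarray:
    """Axial force [BW] at the requested gait percents.

    Linear interpolation of the curve's axial channel, periodic with period
    100 so requests between the last grid point and the wrap interpolate
    toward the cycle start.
    """
    q = np.asarray(gait_pcts, float)
    if np.any((q < 0) | (q >= 100)):
        raise ParameterError("gait_pcts: must lie in [0, 100)")
    return np.interp(q, curve.grid, curve.f_axial, period=100.0)


def scale_to_body_weight(force_bw, body_weight: float):
    """Convert force from body-weight units to Newtons (1 BW * BW[N] = F[N])."""
    if body_weight <= 0:
        raise ParameterError("body_weight: must be > 0")
    return np.asarray(force_bw, float) * body_weight


def build_trajectory(curve: GaitCurve, increment: float, v_max: float) -> Trajectory:
    """Full trajectory preparation: interpolate, merge extrema, profile.

    Chains :func:`interpolate_increments`, :func:`apply_midpoint_rule`,
    :func:`velocity_profile` and :func:`interpolate_force` into a
    :class:`Trajectory` whose angle, velocity and force vectors share one
    length.
    """
    pts = apply_midpoint_rule(interpolate_increments(curve, increment))
    vel = velocity_profile(pts, v_max)
    force = interpolate_force(curve, pts[0])
    return Trajectory(
        gait_pct=pts[0],
        angle=pts[1],
        velocity=vel,
        axial_force=force,
        increment=float(increment),
        v_max=float(v_max),
    )
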