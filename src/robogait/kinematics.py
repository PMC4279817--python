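"""Passive flexion paths and rotation-center estimation.

A *passive flexion path* is the ordered sequence of rigid femur-in-tibia poses
recorded while a joint is flexed along its path of minimal resistance at fixed
angle increments.  Coordinate convention: x medio-lateral (flexion axis),
y posterior-anterior, z distal-to-proximal axial; right-handed; translations
in mm.

The functional joint rotation center is estimated as the *minimal amplitude
point*: the femur-fixed material point whose trajectory in the tibia (base)
frame has least dispersion over the recorded motion.  With poses
``(R_t, d_t)`` the point solves the least-squares problem

    min_p  sum_t || (R_t - R_bar) p + (d_t - d_bar) ||^2

via the normal equations, where bars denote averages over poses.  For motion
about a single fixed axis the center is only determined up to translation
along that axis; the minimum-norm solution along the null direction is
returned (pseudo-inverse with relative tolerance 1e-8) together with a
conditioning diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateMotionError, ParameterError

__all__ = [
    "RigidTransform",
    "PassivePath",
    "RotationCenterResult",
    "generate_passive_path",
    "estimate_rotation_center",
    "recenter_path",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform: 3x3 rotation plus translation [mm]."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ParameterError("rotation must be 3x3 and translation length-3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or abs(
            np.linalg.det(R) - 1.0
        ) > 1e-6:
            raise ParameterError("rotation: not orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, point: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(point, float) + self.translation


@dataclass(frozen=True)
class PassivePath:
    """Ordered rigid poses at fixed flexion-angle increments.

    ``angles[k] = start_angle + k * increment`` for k = 0..K; a 30 deg span at
    a 0.5 deg increment therefore holds 61 poses.
    """

    start_angle: float
    increment: float
    poses: tuple[RigidTransform, ...]

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ParameterError("increment: must be > 0")
        if len(self.poses) < 2:
            raise ParameterError("poses: need at least 2")
        object.__setattr__(self, "poses", tuple(self.poses))

    @property
    def n(self) -> int:
        return len(self.poses)

    @property
    def span(self) -> float:
        """Recorded flexion span [deg]."""
        return (self.n - 1) * self.increment

    @property
    def angles(self) -> np.ndarray:
        return self.start_angle + self.increment * np.arange(self.n)


@dataclass(frozen=True)
class RotationCenterResult:
    """Minimal-amplitude-point estimate.

    Attributes
    ----------
    center : ndarray
        Femur-local rotation center [mm].
    residual_amplitude : float
        RMS amplitude [mm] of the center's base-frame trajectory about its
        mean; zero for ideal single-axis rotation.
    condition : float
        Ratio of largest to second-largest eigenvalue of the normal matrix.
        Near 1 for well-distributed rotation; large when the recorded motion
        barely constrains the center.
    """

    center: np.ndarray
    residual_amplitude: float
    condition: float


def generate_passive_path(
    center: np.ndarray,
    axis: np.ndarray,
    start_angle: float = 50.0,
    increment: float = 0.5,
    span: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PassivePath:
    """Synthesize a passive flexion path by rotation about a fixed axis.

    Stands in for robot-recorded passive flexion: the pose at flexion angle
    ``a`` rotates the femur frame by ``a - start_angle`` about the line
    through ``center`` with direction ``axis`` (so the starting pose is the
    identity), optionally perturbed by seeded zero-mean isotropic Gaussian
    translational noise of standard deviation ``noise_sd`` mm.
    """
    center = np.asarray(center, float)
    axis = np.asarray(axis, float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ParameterError("axis: must be unit length")
    if span <= 0:
        raise ParameterError("span: must be > 0")
    if increment <= 0:
        raise ParameterError("increment: must be > 0")
    n_steps = span / increment
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ParameterError("increment: must divide span")
    if noise_sd < 0:
        raise ParameterError("noise_sd: must be >= 0")
    k = int(round(n_steps))
    rel_angles = np.deg2rad(increment * np.arange(k + 1))
    rots = Rotation.from_rotvec(np.outer(rel_angles, axis)).as_matrix()
    rng = np.random.default_rng(seed)
    poses = []
    for R in rots:
        t = (np.eye(3) - R) @ center
        if noise_sd > 0:
            t = t + rng.normal(0.0, noise_sd, 3)
        poses.append(RigidTransform(R, t))
    return PassivePath(start_angle=start_angle, increment=increment, poses=poses)


def _rotation_range_deg(poses) -> float:
    """Largest geodesic rotation angle [deg] between any pose and the first."""
    R0 = poses[0].rotation
    mags = [
        np.rad2deg(
            np.linalg.norm(Rotation.from_matrix(R0.T @ p.rotation).as_rotvec())
        )
        for p in poses[1:]
    ]
    return float(max(mags))


def estimate_rotation_center(
    poses, min_rotation_deg: float = 5.0
) -> RotationCenterResult:
    """Estimate the joint rotation center as the minimal amplitude point.

    Parameters
    ----------
    poses : sequence of RigidTransform
        At least 3 femur-in-tibia poses spanning a rotation range of at
        least ``min_rotation_deg``.
    min_rotation_deg : float
        Guard against near-degenerate motion; below this range the normal
        equations are ill-conditioned and the estimate meaningless.

    Raises
    ------
    DegenerateMotionError
        If the rotation range is below the guard or the normal matrix is
        effectively rank-deficient beyond the single-axis null direction.
    """
    poses = list(poses)
    if len(poses) < 3:
        raise ParameterError("poses: need at least 3")
    rot_range = _rotation_range_deg(poses)
    if rot_range < min_rotation_deg:
        raise DegenerateMotionError(
            f"rotation range {rot_range:.3g} deg below minimum "
            f"{min_rotation_deg:g} deg",
        )
    Rs = np.stack([p.rotation for p in poses])
    ds = np.stack([p.translation for p in poses])
    Rc = Rs - Rs.mean(axis=0)
    dc = ds - ds.mean(axis=0)
    A = np.einsum("tij,tik->jk", Rc, Rc)
    b = -np.einsum("tij,ti->j", Rc, dc)
    eig = np.sort(np.linalg.eigvalsh(A))[::-1]
    if eig[0] <= 0 or eig[1] / eig[0] < 1e-12:
        raise DegenerateMotionError(
            "normal matrix rank < 2: motion does not constrain a center",
            condition=float("inf"),
        )
    condition = float(eig[0] / eig[1])
    # Single-axis motion leaves A rank-2; pinv returns the minimum-norm
    # solution along the null (axis) direction.
    center = np.linalg.pinv(A, rcond=1e-8) @ b
    residuals = Rc @ center + dc
    residual_amplitude = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return RotationCenterResult(
        center=center, residual_amplitude=residual_amplitude, condition=condition
    )


def recenter_path(path: PassivePath, center: np.ndarray) -> PassivePath:
    """Re-express a passive path with both coordinate origins at ``center``.

    Translating the base and tool origins to the rotation center leaves each
    rotation unchanged and maps each translation d to ``(R - I) c + d``;
    relative motion between consecutive poses is preserved.  Recentering to
    the estimated rotation center moves the center to the origin, which is
    how a robot's flexion axis is corrected after the first recording.
    """
    c = np.asarray(center, float)
    if c.shape != (3,):
        raise ParameterError("center: must be a 3-vector")
    poses = [
        RigidTransform(p.rotation, (p.rotation - np.eye(3)) @ c + p.translation)
        for p in path.poses
    ]
    return PassivePath(
        start_angle=path.start_angle, increment=path.increment, poses=poses
    )
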