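"""Synthetic gait-dynamics curves and cycle-junction correction.

The in vivo reference for a robot-assisted knee-flexion simulation is a set of
curves sampled on a uniform percent-of-gait-cycle grid: flexion angle in
degrees and tibiofemoral contact forces in body-weight (BW) units.  Published
averaged ovine curves are not redistributable, so :func:`generate_gait_template`
produces a parametric stand-in with the same gross features: flexion starting
at the heel-strike minimum (~50 deg), a small (~7 deg) stance excursion during
the stance phase (0-54% of cycle), a large swing flexion peak reaching ~80 deg,
a double-peaked axial stance load in BW, and near-unloaded swing.

Before such a curve is discretized for a robot it must be made periodic at the
cycle junction, otherwise the wrap from 100% back to 0% commands a pulse
movement.  :func:`correct_cycle_junction` concatenates three copies of the
cycle, applies a zero-phase low-pass filter, and keeps the middle copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import ParameterError

__all__ = [
    "GaitCurve",
    "GaitTemplateParams",
    "generate_gait_template",
    "correct_cycle_junction",
    "wrap_discontinuity",
]

_MIN_GRID = 16


@dataclass(frozen=True)
class GaitCurve:
    """Gait-dynamics curves on a uniform percent-of-cycle grid.

    Attributes
    ----------
    grid : ndarray
        Percent-of-gait-cycle values, uniform, ascending, in [0, 100).
    flexion : ndarray
        Knee flexion angle [deg] per grid point.
    f_axial, f_pa, f_ml : ndarray
        Axial, posterior-anterior and medio-lateral contact force [BW].
    """

    grid: np.ndarray
    flexion: np.ndarray
    f_axial: np.ndarray
    f_pa: np.ndarray
    f_ml: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("grid", "flexion", "f_axial", "f_pa", "f_ml"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            arrays[name] = arr
        n = len(self.grid)
        if n < _MIN_GRID:
            raise ParameterError(f"grid: need at least {_MIN_GRID} points, got {n}")
        for name, arr in arrays.items():
            if arr.ndim != 1 or len(arr) != n:
                raise ParameterError(f"{name}: expected 1-d vector of length {n}")
            if not np.all(np.isfinite(arr)):
                raise ParameterError(f"{name}: contains non-finite values")
        if self.grid[0] < 0 or self.grid[-1] >= 100:
            raise ParameterError("grid: values must lie in [0, 100)")
        steps = np.diff(self.grid)
        if np.any(steps <= 0) or np.ptp(steps) > 1e-9:
            raise ParameterError("grid: spacing must be constant and positive")

    @property
    def n(self) -> int:
        return len(self.grid)

    @property
    def spacing(self) -> float:
        """Grid spacing in percent of cycle."""
        return float(self.grid[1] - self.grid[0])

    def channels(self) -> dict[str, np.ndarray]:
        """The four data channels keyed by name (grid excluded)."""
        return {
            "flexion": self.flexion,
            "f_axial": self.f_axial,
            "f_pa": self.f_pa,
            "f_ml": self.f_ml,
        }

    def force(self, component: str) -> np.ndarray:
        """Force channel by component label ('axial' | 'pa' | 'ml')."""
        try:
            return {"axial": self.f_axial, "pa": self.f_pa, "ml": self.f_ml}[component]
        except KeyError:
            raise ParameterError(f"component: unknown force component {component!r}")


@dataclass(frozen=True)
class GaitTemplateParams:
    """Shape parameters of the synthetic gait template.

    Defaults emulate the averaged in vivo ovine gait the simulator targets:
    flexion from 50 deg (heel-strike minimum) over a 30 deg range, stance
    occupying 54% of the cycle with a 7 deg flexion excursion, a double-peak
    axial load topping out at ``axial_peak`` BW, and a near-unloaded swing.
    Transverse (PA/ML) reference forces are scaled copies of the axial curve;
    their gains are dimensionless.
    """

    flexion_start: float = 50.0
    flexion_range: float = 30.0
    stance_fraction: float = 54.0
    stance_flexion_excursion: float = 7.0
    axial_peak: float = 2.2
    swing_load: float = 0.2
    pa_gain: float = 0.25
    ml_gain: float = 0.12
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flexion_range <= 0:
            raise ParameterError("flexion_range: must be > 0")
        if not 0 < self.stance_fraction < 100:
            raise ParameterError("stance_fraction: must be in (0, 100)")
        if self.stance_flexion_excursion < 0:
            raise ParameterError("stance_flexion_excursion: must be >= 0")
        if self.stance_flexion_excursion > self.flexion_range:
            raise ParameterError(
                "stance_flexion_excursion: cannot exceed flexion_range"
            )
        if self.axial_peak <= self.swing_load:
            raise ParameterError("axial_peak: must exceed swing_load")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd: must be >= 0")


def _raised_cosine_bump(g: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """cos^2 bump of unit height with compact support [center-hw, center+hw]."""
    x = (g - center) / halfwidth
    out = np.where(np.abs(x) < 1.0, np.cos(0.5 * np.pi * x) ** 2, 0.0)
    return out


def generate_gait_template(params: GaitTemplateParams, n_grid: int = 200) -> GaitCurve:
    """Generate a synthetic gait-dynamics curve set.

    The flexion angle is built from two smooth sin^2 lobes — a small stance
    lobe peaking mid-stance and a large swing lobe peaking mid-swing — so the
    curve and its slope are continuous across the cycle junction.  The axial
    load is a swing baseline plus two raised-cosine stance bumps (weight
    acceptance and push-off), giving the characteristic double-peak stance
    profile; the second peak is slightly lower than the first.

    Parameters
    ----------
    params : GaitTemplateParams
    n_grid : int
        Number of uniform grid points over [0, 100); at least 16.

    Returns
    -------
    GaitCurve
        Deterministic for identical ``params`` (including seed) and ``n_grid``.
    """
    if n_grid < _MIN_GRID:
        raise ParameterError(f"n_grid: need at least {_MIN_GRID}, got {n_grid}")
    g = np.arange(n_grid) * (100.0 / n_grid)
    st = params.stance_fraction
    sw = 100.0 - st

    stance_lobe = np.where(g < st, np.sin(np.pi * g / st) ** 2, 0.0)
    swing_lobe = np.where(g >= st, np.sin(np.pi * (g - st) / sw) ** 2, 0.0)
    flexion = (
        params.flexion_start
        + params.stance_flexion_excursion * stance_lobe
        + params.flexion_range * swing_lobe
    )

    amp = params.axial_peak - params.swing_load
    # Weight-acceptance peak at ~28% of stance, push-off peak at ~78% of
    # stance, supports chosen so both vanish at heel strike and toe off.
    c1, w1 = 0.28 * st, 0.28 * st
    c2, w2 = 0.78 * st, 0.22 * st
    f_axial = (
        params.swing_load
        + amp * _raised_cosine_bump(g, c1, w1)
        + 0.85 * amp * _raised_cosine_bump(g, c2, w2)
    )
    f_pa = params.pa_gain * f_axial
    f_ml = params.ml_gain * f_axial

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        f_axial = f_axial + rng.normal(0.0, params.noise_sd, n_grid)
        f_pa = f_pa + rng.normal(0.0, params.noise_sd, n_grid)
        f_ml = f_ml + rng.normal(0.0, params.noise_sd, n_grid)

    return GaitCurve(grid=g, flexion=flexion, f_axial=f_axial, f_pa=f_pa, f_ml=f_ml)


def wrap_discontinuity(values: np.ndarray) -> float:
    """Magnitude of the cycle-junction jump of one channel.

    Linearly extrapolates the last two samples by one grid step to the wrap
    position (100% == 0%) and returns |first sample - extrapolation|.
    """
    values = np.asarray(values, dtype=float)
    extrapolated = 2.0 * values[-1] - values[-2]
    return float(abs(values[0] - extrapolated))


def correct_cycle_junction(curve: GaitCurve, cutoff_harmonic: int = 10) -> GaitCurve:
    """Smooth the cycle junction of a gait curve.

    Three copies of each channel are concatenated, a zero-phase 2nd-order
    Butterworth low-pass (forward-backward) with cutoff at ``cutoff_harmonic``
    cycles per gait cycle is applied, and the middle copy is returned.  All
    four channels (flexion and three force components) are filtered
    identically; the grid is unchanged.

    Parameters
    ----------
    curve : GaitCurve
    cutoff_harmonic : int
        Cutoff expressed as a harmonic count of the gait cycle; must be >= 2
        and below the Nyquist harmonic ``n_grid / 2``.
    """
    if cutoff_harmonic < 2:
        raise ParameterError("cutoff_harmonic: must be >= 2")
    nyquist_harmonic = curve.n / 2.0
    if cutoff_harmonic >= nyquist_harmonic:
        raise ParameterError(
            f"cutoff_harmonic: {cutoff_harmonic} is at or above the grid's "
            f"Nyquist harmonic {nyquist_harmonic:g}"
        )
    sos = signal.butter(2, cutoff_harmonic / nyquist_harmonic, output="sos")
    n = curve.n
    filtered = {}
    for name, values in curve.channels().items():
        tripled = np.concatenate([values, values, values])
        smoothed = signal.sosfiltfilt(sos, tripled)
        filtered[name] = smoothed[n : 2 * n]
    return GaitCurve(
        grid=curve.grid.copy(),
        flexion=filtered["flexion"],
        f_axial=filtered["f_axial"],
        f_pa=filtered["f_pa"],
        f_ml=filtered["f_ml"],
    )
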