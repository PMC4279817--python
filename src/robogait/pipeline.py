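"""End-to-end pipeline: template -> trajectory -> execution -> metrics.

Mirrors the workflow of a robot-assisted joint-dynamics experiment on one or
more virtual specimens:

1. generate (or load) the gait-dynamics reference curve and correct its
   cycle junction;
2. discretize it at the chosen increment and build the velocity and axial
   force commands;
3. per specimen: record a noisy passive flexion path about that specimen's
   joint center, estimate the rotation center (minimal amplitude point),
   recenter, and record the corrected path;
4. map the trajectory onto the corrected path, execute it for ``n_cycles``
   with velocity saturation, and sample a trace;
5. bin all retained cycles of all specimens and compute residual-error and
   SD statistics per force component.

Every artifact can be written to an output directory together with a JSON
manifest of the full configuration, making re-runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rgio
from .errors import ParameterError
from .gait import GaitCurve, GaitTemplateParams, correct_cycle_junction, generate_gait_template
from .kinematics import (
    PassivePath,
    estimate_rotation_center,
    generate_passive_path,
    recenter_path,
)
from .metrics import (
    COMPONENTS,
    MetricsResult,
    bin_trace,
    compute_metrics,
    reference_at_bins,
    stack_specimens,
)
from .robot import (
    JointModelParams,
    RobotParams,
    build_loaded_path,
    simulate_execution,
)
from .trajectory import build_trajectory

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full simulation run.

    ``body_weights`` holds one entry per virtual specimen [N]; the default
    four specimens at 300/300/300/350 N match a typical ovine cohort.  The
    per-specimen random streams are derived from ``seed``.
    """

    gait: GaitTemplateParams = field(default_factory=GaitTemplateParams)
    robot: RobotParams = field(default_factory=RobotParams)
    joint: JointModelParams = field(default_factory=JointModelParams)
    increment: float = 0.5
    v_max: float = 10.0
    body_weights: tuple[float, ...] = (300.0, 300.0, 300.0, 350.0)
    n_grid: int = 200
    cutoff_harmonic: int = 10
    joint_center_mm: tuple[float, float, float] = (0.0, 8.0, 15.0)
    path_noise_sd_mm: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ParameterError("increment: must be > 0")
        if self.v_max <= 0:
            raise ParameterError("v_max: must be > 0")
        if not self.body_weights:
            raise ParameterError("body_weights: need at least one specimen")
        if any(bw <= 0 for bw in self.body_weights):
            raise ParameterError("body_weights: must all be > 0")
        if self.path_noise_sd_mm < 0:
            raise ParameterError("path_noise_sd_mm: must be >= 0")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        """Build a config from nested plain dicts, rejecting unknown keys."""
        raw = dict(raw)
        kwargs = {}
        nested = {
            "gait": GaitTemplateParams,
            "robot": RobotParams,
            "joint": JointModelParams,
        }
        for key, klass in nested.items():
            if key in raw:
                sub = raw.pop(key)
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(sub) - known
                if unknown:
                    raise ParameterError(
                        f"{key}: unknown key(s) {', '.join(sorted(unknown))}"
                    )
                kwargs[key] = klass(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown key(s) {', '.join(sorted(unknown))}")
        for key in ("body_weights", "joint_center_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**kwargs, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PipelineResult:
    """Everything a run produces, keyed for inspection."""

    curve: GaitCurve
    corrected: GaitCurve
    trajectory: object
    paths: tuple[PassivePath, ...]
    center_errors_mm: tuple[float, ...]
    traces: tuple
    metrics: dict[str, MetricsResult]


def _specimen_seed(base: int, i: int, stream: int) -> int:
    # distinct, reproducible, and well below 2**31
    return (base * 9973 + i * 613 + stream * 101) % (2**31 - 1)


def _passive_span(config: RunConfig, curve: GaitCurve, traj) -> tuple[float, float]:
    """Passive-recording span: the raw curve's flexion range rounded outward
    to the increment lattice (the recording precedes trajectory preparation),
    widened if needed to cover every trajectory angle."""
    inc = config.increment
    lo = np.floor(curve.flexion.min() / inc + 1e-9) * inc
    hi = np.ceil(curve.flexion.max() / inc - 1e-9) * inc
    lo = min(lo, np.floor((traj.angle.min() - lo) / inc + 0.5) * inc + lo)
    hi = max(hi, np.ceil((traj.angle.max() - lo) / inc - 0.5) * inc + lo)
    return float(lo), float(hi - lo)


def _record_passive_paths(config: RunConfig, start: float, span: float):
    """Record, recenter and re-record one passive path per specimen."""
    axis = np.array([1.0, 0.0, 0.0])  # flexion about the medio-lateral axis
    center = np.asarray(config.joint_center_mm, float)
    paths, errors = [], []
    for i in range(len(config.body_weights)):
        first = generate_passive_path(
            center,
            axis,
            start_angle=start,
            increment=config.increment,
            span=span,
            noise_sd=config.path_noise_sd_mm,
            seed=_specimen_seed(config.seed, i, 0),
        )
        est = estimate_rotation_center(first.poses)
        errors.append(float(np.linalg.norm(est.center - center)))
        # axis correction: re-record about the estimated center
        second = generate_passive_path(
            center,
            axis,
            start_angle=start,
            increment=config.increment,
            span=span,
            noise_sd=config.path_noise_sd_mm,
            seed=_specimen_seed(config.seed, i, 1),
        )
        paths.append(recenter_path(second, est.center))
    return paths, errors


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute the full simulation and return (and optionally write) results.

    Identical configs produce identical results; with ``outdir`` set, also
    byte-identical files plus a ``manifest.json`` recording the config.
    """
    curve = generate_gait_template(config.gait, config.n_grid)
    corrected = correct_cycle_junction(curve, config.cutoff_harmonic)
    traj = build_trajectory(corrected, config.increment, config.v_max)

    start, span = _passive_span(config, curve, traj)
    paths, center_errors = _record_passive_paths(config, start, span)

    traces = []
    binned = {comp: [] for comp in COMPONENTS}
    for i, (bw, path) in enumerate(zip(config.body_weights, paths)):
        loaded = build_loaded_path(traj, path, body_weight=bw)
        joint = dataclasses.replace(
            config.joint, seed=_specimen_seed(config.seed, i, 2)
        )
        trace = simulate_execution(loaded, path, config.robot, joint)
        traces.append(trace)
        for comp in COMPONENTS:
            binned[comp].append(
                bin_trace(trace, bw, config.robot.n_precondition, component=comp)
            )

    metrics = {}
    for comp in COMPONENTS:
        stacked = stack_specimens(binned[comp])
        reference = reference_at_bins(corrected, component=comp)
        metrics[comp] = compute_metrics(stacked, reference)

    result = PipelineResult(
        curve=curve,
        corrected=corrected,
        trajectory=traj,
        paths=tuple(paths),
        center_errors_mm=tuple(center_errors),
        traces=tuple(traces),
        metrics=metrics,
    )
    if outdir is not None:
        _write_artifacts(result, config, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rgio.write_gait_curve(result.curve, outdir / "gait_template.csv")
    rgio.write_gait_curve(result.corrected, outdir / "gait_corrected.csv")
    rgio.write_trajectory(result.trajectory, outdir / "trajectory.csv")
    for i, (path, trace) in enumerate(zip(result.paths, result.traces)):
        rgio.write_passive_path(path, outdir / f"passive_path_{i}.csv")
        rgio.write_trace(trace, outdir / f"trace_{i}.csv")
    rgio.write_metrics(result.metrics, outdir / "metrics.json")
    manifest = {
        "config": config.to_dict(),
        "center_errors_mm": list(result.center_errors_mm),
        "cycle_period_s": [t.cycle_period for t in result.traces],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
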