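"""Fidelity statistics comparing simulated forces to the in vivo reference.

After discarding preconditioning cycles, the measured forces of each retained
cycle are averaged into 100 one-percent gait bins and converted to body-weight
(BW) units, giving a value per (bin k, specimen i, cycle j).  Two summaries
are computed per force component:

* residual error against the reference curve interpolated at each percent,

      eps_k     = sqrt( 1/(m n) * sum_ij (F_kij - F_k,ref)^2 )
      eps_total = sqrt( 1/p * sum_k eps_k^2 )

* reproducibility, as the per-bin standard deviation over the m*n cells and
  its root-mean-square across bins,

      sigma_total = sqrt( 1/p * sum_k sigma_k^2 )

with p = 100 bins.  The SD convention defaults to the sample SD (ddof=1);
``ddof=0`` selects the population form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BinningError, ParameterError
from .gait import GaitCurve
from .robot import RobotTrace

__all__ = [
    "BinnedForces",
    "MetricsResult",
    "bin_trace",
    "stack_specimens",
    "reference_at_bins",
    "residual_error",
    "sd_metrics",
    "compute_metrics",
]

N_BINS = 100

COMPONENTS = ("axial", "pa", "ml")


@dataclass(frozen=True)
class BinnedForces:
    """Per-bin force cells, shape (p bins, m specimens, n cycles), in BW."""

    values: np.ndarray
    component: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 3:
            raise ParameterError("values: expected (bins, specimens, cycles)")
        if not np.all(np.isfinite(v)):
            raise ParameterError("values: contains non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MetricsResult:
    """Residual-error and SD curves per 1% bin plus their scalar totals [BW]."""

    eps_curve: np.ndarray
    eps_total: float
    sd_curve: np.ndarray
    sd_total: float


def bin_trace(
    trace: RobotTrace,
    body_weight: float,
    n_precondition: int,
    component: str = "axial",
    n_bins: int = N_BINS,
) -> BinnedForces:
    """Average one specimen's trace into per-(bin, cycle) cells in BW.

    Bin k covers gait percent [k, k+1).  Cycles with index below
    ``n_precondition`` are discarded; each retained (bin, cycle) cell is the
    mean of its samples divided by the body weight.  An empty cell raises
    :class:`BinningError` naming the bin.
    """
    if body_weight <= 0:
        raise ParameterError("body_weight: must be > 0")
    n_cycles = int(trace.cycle.max()) + 1
    if n_cycles <= n_precondition:
        raise ParameterError(
            f"n_precondition: trace spans {n_cycles} cycles, cannot discard "
            f"{n_precondition}"
        )
    keep = trace.cycle >= n_precondition
    force_bw = trace.force(component)[keep] / body_weight
    cyc = trace.cycle[keep] - n_precondition
    bins = np.minimum((trace.gait_pct[keep] / (100.0 / n_bins)).astype(int), n_bins - 1)
    n_kept = n_cycles - n_precondition

    flat = bins * n_kept + cyc
    size = n_bins * n_kept
    sums = np.bincount(flat, weights=force_bw, minlength=size)
    counts = np.bincount(flat, minlength=size)
    if np.any(counts == 0):
        empty = int(np.argmax(counts == 0))
        raise BinningError(
            f"bin {empty // n_kept} has no samples in cycle {empty % n_kept}"
        )
    cells = (sums / counts).reshape(n_bins, 1, n_kept)
    return BinnedForces(values=cells, component=component)


def stack_specimens(binned_list) -> BinnedForces:
    """Concatenate per-specimen binned forces along the specimen axis."""
    binned_list = list(binned_list)
    if not binned_list:
        raise ParameterError("binned_list: must be non-empty")
    comp = binned_list[0].component
    if any(b.component != comp for b in binned_list):
        raise ParameterError("binned_list: mixed force components")
    values = np.concatenate([b.values for b in binned_list], axis=1)
    return BinnedForces(values=values, component=comp)


def reference_at_bins(
    curve: GaitCurve, component: str = "axial", n_bins: int = N_BINS
) -> np.ndarray:
    """Reference force [BW] interpolated at the bin centers (k + 0.5)%."""
    centers = (np.arange(n_bins) + 0.5) * (100.0 / n_bins)
    return np.interp(centers, curve.grid, curve.force(component), period=100.0)


def residual_error(
    binned: BinnedForces, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-bin RMS residual against the reference and its total, in BW."""
    ref = np.asarray(reference, float)
    if ref.shape != (binned.p,):
        raise ParameterError(
            f"reference: expected length {binned.p}, got shape {ref.shape}"
        )
    dev = binned.values - ref[:, None, None]
    eps_curve = np.sqrt(np.mean(dev**2, axis=(1, 2)))
    eps_total = float(np.sqrt(np.mean(eps_curve**2)))
    return eps_curve, eps_total


def sd_metrics(binned: BinnedForces, ddof: int = 1) -> tuple[np.ndarray, float]:
    """Per-bin SD over the (specimen, cycle) cells and its total, in BW."""
    p, m, n = binned.values.shape
    if m * n < 2:
        raise ParameterError("sd_metrics: need at least 2 cells per bin")
    cells = binned.values.reshape(p, m * n)
    sd_curve = np.std(cells, axis=1, ddof=ddof)
    sd_total = float(np.sqrt(np.mean(sd_curve**2)))
    return sd_curve, sd_total


def compute_metrics(
    binned: BinnedForces, reference: np.ndarray, ddof: int = 1
) -> MetricsResult:
    """Bundle residual-error and SD summaries for one force component."""
    eps_curve, eps_total = residual_error(binned, reference)
    sd_curve, sd_total = sd_metrics(binned, ddof=ddof)
    return MetricsResult(
        eps_curve=eps_curve,
        eps_total=eps_total,
        sd_curve=sd_curve,
        sd_total=sd_total,
    )
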