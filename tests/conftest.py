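import numpy as np
import pytest

from robogait import (
    GaitCurve,
    GaitTemplateParams,
    correct_cycle_junction,
    generate_gait_template,
)


@pytest.fixture(scope="session")
def default_curve() -> GaitCurve:
    return generate_gait_template(GaitTemplateParams(), n_grid=200)


@pytest.fixture(scope="session")
def corrected_curve(default_curve) -> GaitCurve:
    return correct_cycle_junction(default_curve, cutoff_harmonic=10)


def make_curve(flexion, f_axial=None, n=None) -> GaitCurve:
    """Build a GaitCurve from an explicit flexion vector (uniform grid)."""
    flexion = np.asarray(flexion, float)
    n = len(flexion)
    grid = np.arange(n) * (100.0 / n)
    if f_axial is None:
        f_axial = np.full(n, 0.5)
    f_axial = np.asarray(f_axial, float)
    return GaitCurve(
        grid=grid,
        flexion=flexion,
        f_axial=f_axial,
        f_pa=0.25 * f_axial,
        f_ml=0.12 * f_axial,
    )


@pytest.fixture(scope="session")
def ramp_curve() -> GaitCurve:
    """Monotone flexion ramp 50 -> 80 deg over one segment."""
    return make_curve(np.linspace(50.0, 80.0, 32))
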