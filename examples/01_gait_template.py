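"""Generate a synthetic gait-dynamics template and correct its cycle junction.

The template stands in for averaged in vivo ovine knee curves: flexion angle
and contact forces (in body-weight units) over one gait cycle.
"""

import numpy as np

from robogait import GaitTemplateParams, correct_cycle_junction, generate_gait_template

curve = generate_gait_template(GaitTemplateParams(), n_grid=200)
print(f"flexion span: {curve.flexion.min():.1f} .. {curve.flexion.max():.1f} deg")
stance = curve.grid < 54.0
print(f"stance flexion excursion: {np.ptp(curve.flexion[stance]):.2f} deg")
print(f"peak axial load: {curve.f_axial.max():.2f} BW, "
      f"swing load: {curve.f_axial[~stance].max():.2f} BW")

corrected = correct_cycle_junction(curve, cutoff_harmonic=10)
print(f"junction-corrected start angle: {corrected.flexion[0]:.3f} deg "
      f"(raw {curve.flexion[0]:.3f} deg)")
# The corrected curve wraps smoothly from 100% back to 0%, so repeating the
# cycle on a robot produces no pulse movement at the junction.
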