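"""Mach bands: illusory bright and dark strips flanking a luminance ramp.

The percept profile overshoots just inside the high plateau and
undershoots just inside the low plateau — bands that are absent from the
stimulus.  They arise from collinear facilitation of the units responding
to the diffuse vertical edge formed by the ramp.
"""

from v1bright import ModelParams, make_mach, static_pipeline
from v1bright.analysis import brightness_profile

stim = make_mach(size=128, ramp_width_frac=0.25, low_lum=0.2, high_lum=0.8)
run = static_pipeline(stim, ModelParams())

prof = brightness_profile(run.percept, "row", 64)
stim_prof = brightness_profile(stim, "row", 64)

undershoot = prof[:48].min() - stim_prof[0]     # low-side plateau
overshoot = prof[80:].max() - stim_prof[-1]     # high-side plateau

print(f"stimulus plateaus:        {stim_prof[0]:.3f} -> {stim_prof[-1]:.3f}")
print(f"dark band (undershoot):   {undershoot:+.4f}")
print(f"bright band (overshoot):  {overshoot:+.4f}")
print("Nonzero under/overshoots of opposite sign are the Mach bands; the"
      " stimulus profile itself is monotone.")
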