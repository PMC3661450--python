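"""Dynamic brightness induction with sinusoidally modulated flanks.

Variant A: a static central gray band (with thin bars over the central
receptive field) between two flanks whose luminance is modulated at 2 Hz.
The central band's perceived brightness oscillates at the flank frequency
in antiphase — phase-locked induction from outside the classical RF.

Variant B: no light in the central region; with no inherent activity to
modulate, induction is lost.
"""

import numpy as np

from v1bright import ModelParams, make_rossi_paradiso, dynamic_pipeline
from v1bright.analysis import phase_locking

params = ModelParams()
reports = {}
for variant in ("A", "B"):
    seq = make_rossi_paradiso(size=(64, 96), variant=variant,
                              mod_freq_hz=2.0, tau_ms=params.tau_ms,
                              n_periods=3)
    # three scales: every modeled receptive field fits inside the central
    # region, so the flanks stay outside the classical RFs as in the
    # physiological display
    run = dynamic_pipeline(seq, params, n_scales=3)
    series = run.central_brightness_series()
    reports[variant] = phase_locking(series, seq.meta["frames_per_period"],
                                     mod_freq=2.0)

a, b = reports["A"], reports["B"]
print(f"variant A: modulation amplitude {a.amplitude:.4f}, "
      f"phase vs flanks {a.phase_diff:+.2f} rad (pi = antiphase)")
print(f"variant B: modulation amplitude {b.amplitude:.4f}")
print(f"amplitude ratio B/A: {b.amplitude / a.amplitude:.2f}")
print("Variant A should show a clear amplitude with phase near +/-pi;"
      " variant B's amplitude collapses (no activity, no induction).")
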