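"""White effect: equal gray patches interrupting the bright and the dark
bars of a square-wave grating are perceived differently.

The patch interrupting a bright bar (flanked laterally by dark bars) is
perceived darker — the direction opposite to plain lateral contrast, which
is what makes the effect diagnostic: it requires the grating context, not
just the nearest neighbors.
"""

from v1bright import ModelParams, make_white, static_pipeline

stim = make_white(size=128, n_bars=8, patch_len_frac=0.25,
                  lum_black=0.0, lum_white=1.0, patch_lum=0.5)
run = static_pipeline(stim, ModelParams())
pm = run.percept.pixels

# bar width 16: the left patch interrupts bright bar 2 (cols 32:48), the
# right patch interrupts dark bar 5 (cols 80:96)
left = pm[48:80, 32:48].mean()
right = pm[48:80, 80:96].mean()

print(f"stimulus patch luminance (both):        0.500")
print(f"perceived patch in the bright bar:      {left:.3f}")
print(f"perceived patch in the dark bar:        {right:.3f}")
print(f"difference (dark-bar - bright-bar):     {right - left:+.3f}")
print("A positive difference reproduces the White effect: the patch on the"
      " bright bar looks darker despite its dark lateral flanks.")
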