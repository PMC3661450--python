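# Simultaneous brightness contrast, two square half-fields (128 x 256).
stimulus:
  generator: sbc
  args:
    size: 128
    patch_frac: 0.25
    left_bg: 1.0
    right_bg: 0.0
    patch_lum: 0.5
params: {}
seed: 0
out: runs/sbc
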