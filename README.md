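# v1bright

A neurodynamical model of brightness induction in primary visual cortex
(V1). Brightness induction — the change in the perceived intensity of a
surface caused by the luminance of its surroundings — is modeled here as
an emergent property of the horizontal (contextual) circuitry of V1,
rather than imposed through hand-tuned filters or inference rules.

The package is aimed at computational neuroscientists and vision
researchers who want to simulate classical brightness illusions
(simultaneous brightness contrast, grating induction, the White effect,
Mach bands, the Chevreul staircase) and dynamic, phase-locked brightness
induction from temporally modulated surrounds, and to inspect the
underlying circuit variables while they happen.

## The model

A luminance image I is decomposed with an undecimated oriented wavelet
transform (à trous, cubic B-spline) into full-resolution planes w_{s,o}
(scale s, orientation o ∈ {0°, 45°, 90°, 135°}) plus a residual:

    I = Σ_{s,o} w_{s,o} + c_r .

Coefficients are half-wave rectified into ON/OFF channels and normalized
into (1, 3]; they drive a recurrent excitatory/inhibitory rate network in
which every grid position holds a hypercolumn of unit pairs (x, y) per
(scale, orientation, polarity):

    ẋ = −x − Σ_Δθ ψ(Δθ) g_y(y) + J0 g_x(x) + Σ J g_x + I_drive + I0 + noise
    ẏ = −y + g_x(x) + Σ W g_x + Ic + I_norm

J implements bow-tie collinear excitation, W flanking disynaptic
inhibition (both factorized with a Gaussian scale-interaction term), ψ
in-hypercolumn inhibition and I_norm divisive normalization. The perceived
image replaces each coefficient by r·w, where r = (ε+ᾱ)/(ε+ᾱ₀) compares
the unit's temporally averaged firing ᾱ against the context-free baseline
ᾱ₀ (lateral connections off), and applies the exact inverse transform.
Activity above baseline brightens what the coefficient encodes; activity
below baseline fades it toward its surround.

## Worked example

```python
from v1bright import ModelParams, make_sbc, static_pipeline

stim = make_sbc(size=128, left_bg=1.0, right_bg=0.0, patch_lum=0.5)
run = static_pipeline(stim, ModelParams())
pm = run.percept.pixels
print(f"patch on bright field: {pm[48:80,  48: 80].mean():.3f}")
print(f"patch on dark field:   {pm[48:80, 176:208].mean():.3f}")
```

```
patch on bright field: 0.482
patch on dark field:   0.518
```

Both patches have luminance 0.500; the model perceives the patch on the
dark field as brighter and the one on the bright field as darker —
simultaneous brightness contrast. `run.response.alpha` /
`run.response.alpha0` expose the averaged unit activities behind the
percept, and `run.pyramid` the wavelet coefficients.

The `examples/` directory contains one short script per capability
(static illusions, dynamic flank-modulated induction, spatial-frequency
gain); each prints the quantities it computes and what they mean. A thin
CLI mirrors the pipelines:

```bash
v1bright simulate-static  --config examples/sbc.yaml --out runs/sbc
v1bright simulate-dynamic --seed 1 --out runs/dyn
v1bright gain-curve       --out runs/gain
```

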