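# Methods

`v1bright` models brightness induction as an emergent property of
contextual interactions in primary visual cortex. The pipeline has three
stages: a linear, invertible front-end that mimics the multiscale,
multiorientation analysis performed by V1 receptive fields; a recurrent
excitatory/inhibitory rate network with orientation-, position- and
scale-selective horizontal connectivity; and a reconstruction stage that
folds the network's activity back through the inverse transform to produce
a perceived-brightness image.

## Wavelet front-end

The decomposition is an undecimated (a trous) scheme built on the cubic
B-spline kernel [1,4,6,4,1]/16 with hole spacing 2^(s-1) at level s. The
detail at each scale (difference of successive smoothings) is split exactly
into four oriented planes — horizontal, vertical and two diagonals — using
the separable structure of the 2-D smoothing:

    1 - SrSc = (1-Sr)Sc + Sr(1-Sc) + (1-Sr)(1-Sc),

with the doubly high-pass term split into the two diagonal planes by
diagonally holed smoothings, symmetrized so that horizontal mirroring maps
the 45 deg plane onto the 135 deg plane. Every plane has the resolution of
the input, the transform commutes with translation (under the wrap
boundary rule), and the sum of all planes plus the residual equals the
input to machine precision — the property that makes percept
reconstruction possible. Boundary handling is symmetric (mirror) by
default, avoiding spurious edge responses that would themselves induce
brightness artifacts; the exactly periodic "wrap" rule is available and is
used for full-field periodic stimuli and equivariance checks.

Coefficients are half-wave rectified into ON (positive) and OFF (negative)
channels, preserving contrast polarity as in the retinogeniculate pathway.
A single affine map — computed from the global minimum and maximum of the
rectified magnitudes over all positions, scales, orientations, polarities
and (for sequences) frames — takes magnitudes into (norm_lo, norm_hi] =
(1, 3]; exact zeros stay zero, so silent units receive no input. The
normalization makes the drive invariant to global contrast scaling.

## Cortical network

Each grid position carries a hypercolumn of excitatory/inhibitory unit
pairs, one per (scale, orientation, polarity). With time in units of the
membrane time constant tau (10 ms):

    dx/dt = -x - sum_dtheta psi(dtheta) g_y(y) + J0 g_x(x)
            + sum J g_x + I_drive + I0 + noise
    dy/dt = -y + g_x(x) + sum W g_x + Ic + I_norm

g_x is threshold-linear with threshold Tx = 1 and saturation 1; g_y is
threshold-linear with two segments (slopes 0.21 and 2.5, knee 1.2).
Monosynaptic excitation J links near-coaligned, similarly oriented units
along their common axis (bow-tie geometry); disynaptic inhibition W links
flanking, non-aligned pairs. Both follow the published contour-integration
connectivity formulas, with the geometric gate constants exposed in
`ModelParams`. Coupling between scales factorizes into the spatial kernel
times a Gaussian Gs(s,s') = exp(-(s-s')^2 / 2 sigma^2) (sigma = 1 octave,
truncated beyond 2 octaves). psi spreads inhibition within a hypercolumn
across orientation differences (1, 0.8, 0 at 0, 45, >=90 deg). I_norm is a
divisive-normalization current proportional to the squared local mean
firing rate. ON and OFF channels evolve as two independent networks.
Integration is first-order forward Euler with dt = 0.1 tau.

Three adaptations connect this connectivity — originally formulated for a
sparse lattice of discrete edge elements — to the dense undecimated
wavelet representation:

- **Receptive-field-proportional reach.** The lateral tables are dilated
  per scale pair (factor 2^(max(s,s')-1); weights divided by the squared
  dilation), so connection distances are measured in units of the coarser
  receptive field involved. Without this, the 2-4 px thick coefficient
  bands that any feature produces at every scale fall inside the flanker
  geometry of their own fine-scale units and every feature suppresses
  itself.
- **Extra-classical inhibition onset.** W starts beyond the receptive
  field radius (w_min_dist = 2.5 scale units; the B3 footprint spans 5
  units). Units whose receptive fields overlap represent the same feature
  and share an inhibitory pool rather than suppressing each other.
- **Redundancy gain.** In the undecimated grid a single feature element
  activates a receptive-field-sized patch of redundant units, inflating
  lateral sums by roughly the filter footprint. A global lateral gain
  (default 0.125) rescales both J and W into the regime where lateral
  inputs are comparable to the drive rather than an order of magnitude
  larger.

The normalization pool likewise scales with the receptive field
(norm_radius = 2 scale units, dilated per scale), making I_norm a local
contrast-energy measure at each scale.

These choices were calibrated jointly against the direction (not the
magnitude) of the qualitative battery — simultaneous contrast at two patch
scales, grating induction, the White effect, Mach bands — holding the
published connectivity formulas and firing functions fixed.

## Steady state and averaging

With a static drive the network settles (after a discarded transient of 20
tau) into a steady state that is oscillatory for structured inputs; the
model output is the average of g_x over 12 tau. The context-free baseline
alpha0 comes from an identical run (same seed, same noise realization)
with J and W disabled. Forward Euler sustains the steady-state oscillation
with amplitude roughly proportional to dt; the cycle-aligned mean of the
output converges at first order in dt (the step-halving test averages over
an integer number of measured oscillation cycles for exactly this reason —
a 12-tau window cuts a non-integer number of ~3.6-tau cycles and is
phase-sensitive at the few-percent level).

Background input I0 = 0.85 is subthreshold: the context-free rest state is
x* = I0 - sum psi g_y(Ic) < Tx with zero firing, so "inherent activity"
exists only where the stimulus provides it — the property that makes
induction vanish in the dark-center dynamic stimulus. Additive uniform
background noise (amplitude 0.1 I0, seeded) is part of the default
operating point; invariance tests switch it off.

## Percept reconstruction

Each coefficient is reweighted by the contextual modulation ratio
r = (eps + alpha) / (eps + alpha0) of its matching polarity channel,
clipped to [0.25, 4]; the residual plane passes through unchanged,
anchoring mean luminance. The rule reduces to the identity wherever
context leaves activity unchanged, preserves contrast polarity through the
ON/OFF split, and is the package's reading of "activity acts as a
weighting function of the coefficients" — the printed form of the
weighting is not recoverable from the source text. Percepts are not
re-clipped to [0, 1]: over- and undershoots are the phenomena (Mach
bands). In the dynamic case the same rule is applied per frame with the
instantaneous (unaveraged) g_x and a per-frame lateral-free baseline.

## Dynamic stimuli

A frame sequence advances one frame per membrane time constant; a stimulus
modulated sinusoidally at temporal frequency f is sampled so that one
period spans P = 1/(f tau) frames (2 Hz at tau = 10 ms gives 50 frames per
period). The flank-modulation display consists of three equal vertical
regions; the flanks oscillate sinusoidally about the mean luminance while
the central region is static (variant A: mean luminance with two thin
bright and two thin dark full-height bars over the central receptive
field; variant B: no light). Defaults are 64 x 96 px, 2 Hz, modulation
depth 0.4, three periods.

The flank display is analyzed with three wavelet scales: the coarsest
modeled receptive field (20 px) then fits inside the 32 px central
region, so the flanks remain outside the classical receptive fields of
every modeled "center" unit, as the paradigm requires. (A fourth scale
would have 40 px receptive fields that physically cover the lit flanks,
and the resulting coefficient spill produces a spurious brightness
modulation of the dark center in the no-light control.)  Perceived
central brightness is measured over the middle half of the central
region, away from the region borders, matching where the recordings
probe.

Phase locking is quantified by projecting the raw response series onto
sine/cosine at the modulation frequency over an integer number of periods;
the phase is reported relative to the flank sinusoid. The square-window
smoothing (window = one period) described for the neurophysiological
analysis is computed and returned for display, but amplitude and phase are
estimated from the raw series: a discrete boxcar exactly one period wide
nulls the component it is meant to measure.

## Spatial-frequency gain

For the gain analysis, full-field sinusoidal gratings (one frequency per
wavelet passband, at the band's peak frequency; contrast 0.4; 128 x 128)
are run through the full static pipeline under the wrap boundary rule
(exact for periodic stimuli); the gain at each frequency is the amplitude
of the percept's Fourier component at the input frequency divided by the
stimulus amplitude, and the reported slope is the ordinary-least-squares
fit of log10(gain) against log10(frequency). With lateral connections
disabled the modulation ratio is identically 1 and the curve is flat —
the slope measures the contextual circuitry, not the front-end.

With the full circuit, every grating is suppressed (gains below 1:
iso-orientation surround suppression of extended textures), and because
the lateral connectivity scales with the receptive field the suppression
is nearly equal across scales: the resulting gain curve is close to flat
and its fitted slope is near zero. A markedly positive slope (stronger
relative attenuation of low frequencies) arises in this architecture only
when lateral distances are measured in fixed pixel units at every scale —
coarse-scale coefficient bands are then denser relative to the kernel and
absorb more flanker inhibition — but that same regime inverts the
direction of the contrast illusions, so the receptive-field-proportional
metric is retained and the near-flat curve is reported as the model's
behavior.

## Problem sizes and defaults

Static stimuli default to 128 x 128 (the two-field simultaneous-contrast
display is 128 x 256 so each half-field is square); dynamic stimuli to
64 x 96 with three modulation periods. Four wavelet scales are used at
these sizes. These sizes resolve four octaves of structure while keeping
single runs at desk scale; all dimensions are configurable.

## What the synthetic battery does and does not show

All inputs are generated programmatically: noiseless geometric displays
with exact luminances, plus deterministic sinusoidal modulations. Passing
the battery shows that the circuit reproduces the direction and spatial
structure of the classical induction effects and the phase relation of
dynamic induction under idealized conditions. It does not show calibration
against psychophysical magnitudes (no luminance-to-candela mapping, no
observer model), robustness to natural-image statistics, or chromatic
effects — all outside the model's scope.

## Known limitations

- The connectivity constants and thresholds are taken from the published
  contour-integration model family and adapted to the dense wavelet
  representation as described above; the original implementation's exact
  supplementary values are not recoverable from the source text, so
  magnitudes of the reproduced effects should be read qualitatively.
- Whether ON and OFF channels share inhibitory pools is unspecified in the
  source; they are modeled as independent (the simplest reading), which
  makes the polarity-swap symmetry exact.
- The steady-state oscillation amplitude is partially numerical (forward
  Euler); oscillation-based coding questions are out of scope.
- Percept magnitudes depend on the clipping bounds [0.25, 4] of the
  modulation ratio; directions do not, over the ranges tested.
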