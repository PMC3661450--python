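"""Programmatic stimulus battery for brightness-induction experiments.

All generators emit luminance arrays on a fixed [0, 1] scale, are fully
deterministic, and mirror the classical psychophysics displays: simultaneous
brightness contrast (SBC), grating induction, the White effect, Mach bands,
the Chevreul staircase, and the dynamic flank-modulation displays of Rossi &
Paradiso.  Static stimuli are plain 2-D images; dynamic stimuli are
:class:`FrameSequence` objects whose frame period equals one membrane time
constant of the downstream cortical network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSequence",
    "make_sbc",
    "make_grating_induction",
    "make_white",
    "make_mach",
    "make_chevreul",
    "make_rossi_paradiso",
    "make_sine_grating",
    "DEFAULT_BAR_SPEC",
]

MIN_SIZE = 16


def _check_lum(*values: float) -> None:
    for v in values:
        if not np.isfinite(v) or not (0.0 <= v <= 1.0):
            raise ValueError(f"luminance {v!r} outside [0, 1]")


def _check_size(h: int, w: int) -> None:
    if h < MIN_SIZE or w < MIN_SIZE:
        raise ValueError(f"image dimensions {h}x{w} below minimum {MIN_SIZE}")


@dataclass
class FrameSequence:
    """An ordered stack of equally-sized luminance frames.

    ``frame_period`` is expressed in units of the network membrane time
    constant tau: the cortical simulation advances the stimulus by one frame
    per ``frame_period`` membrane time constants (default 1).
    """

    frames: np.ndarray  # (n_frames, H, W)
    frame_period: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need >= 2 frames of identical shape")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if not np.isfinite(self.frames).all():
            raise ValueError("non-finite frame values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __iter__(self):
        return iter(self.frames)


def make_sbc(
    size: int = 128,
    patch_frac: float = 0.25,
    left_bg: float = 1.0,
    right_bg: float = 0.0,
    patch_lum: float = 0.5,
) -> np.ndarray:
    """Simultaneous brightness contrast: two square half-fields, one bright
    and one dark, each with a centered square test patch of identical
    luminance.  Returns a (size, 2*size) image so each half-field is square
    and ``patch_frac`` is the patch side as a fraction of the half-field
    side.
    """
    _check_lum(left_bg, right_bg, patch_lum)
    if not (0.0 < patch_frac < 0.5):
        raise ValueError("patch_frac must lie in (0, 0.5)")
    _check_size(size, 2 * size)
    img = np.empty((size, 2 * size), dtype=float)
    img[:, :size] = left_bg
    img[:, size:] = right_bg
    a = int(round(patch_frac * size))
    r0 = (size - a) // 2
    for c_center in (size // 2, size + size // 2):
        c0 = c_center - a // 2
        img[r0 : r0 + a, c0 : c0 + a] = patch_lum
    return img


def make_grating_induction(
    size: int = 128,
    inducer_freq: float = 4.0,
    test_height_frac: float = 0.25,
    mean_lum: float = 0.5,
    contrast: float = 0.5,
) -> np.ndarray:
    """Grating induction: upper and lower in-phase sinusoidal inducer
    gratings (luminance varying along the horizontal axis) separated by a
    uniform central test band at the mean luminance.
    """
    _check_lum(mean_lum)
    if contrast < 0 or contrast > min(mean_lum, 1.0 - mean_lum):
        raise ValueError("contrast must satisfy 0 <= c <= min(mean, 1-mean)")
    _check_size(size, size)
    band_h = int(round(test_height_frac * size))
    if band_h >= size:
        raise ValueError("test band taller than image")
    x = np.arange(size)
    inducer_row = mean_lum + contrast * np.sin(2.0 * np.pi * inducer_freq * x / size)
    img = np.tile(inducer_row, (size, 1))
    r0 = (size - band_h) // 2
    img[r0 : r0 + band_h, :] = mean_lum
    return img


def make_white(
    size: int = 128,
    n_bars: int = 8,
    patch_len_frac: float = 0.25,
    lum_black: float = 0.0,
    lum_white: float = 1.0,
    patch_lum: float = 0.5,
) -> np.ndarray:
    """White effect: a vertical square-wave grating with one gray patch
    interrupting a bright bar (left half) and one interrupting a dark bar
    (right half).  Both patches have exactly ``patch_lum`` and span one bar
    width.  The left patch is therefore flanked laterally by dark bars and
    bordered coaxially by the remaining bright bar — the configuration
    perceived darker in the White effect.
    """
    _check_lum(lum_black, lum_white, patch_lum)
    if n_bars % 2 != 0 or n_bars < 4:
        raise ValueError("n_bars must be even and >= 4")
    _check_size(size, size)
    bar_w = size // n_bars
    if bar_w < 1:
        raise ValueError("patch wider than a bar")
    img = np.empty((size, size), dtype=float)
    for i in range(n_bars):
        lum = lum_white if i % 2 == 0 else lum_black
        img[:, i * bar_w : (i + 1) * bar_w if i < n_bars - 1 else size] = lum
    patch_h = int(round(patch_len_frac * size))
    if patch_h < 1 or patch_h > size:
        raise ValueError("invalid patch_len_frac")
    r0 = (size - patch_h) // 2

    def nearest_with_parity(target: float, parity: int) -> int:
        cands = [i for i in range(n_bars) if i % 2 == parity]
        return min(cands, key=lambda i: (abs(i - target), i))

    # bright bars at even indices; left patch in a bright bar, right in a dark
    i_left = nearest_with_parity(n_bars / 4, 0)
    i_right = nearest_with_parity(3 * n_bars / 4, 1)
    for i in (i_left, i_right):
        img[r0 : r0 + patch_h, i * bar_w : (i + 1) * bar_w] = patch_lum
    return img


def make_mach(
    size: int = 128,
    ramp_width_frac: float = 0.25,
    low_lum: float = 0.2,
    high_lum: float = 0.8,
) -> np.ndarray:
    """Mach-band stimulus: a low plateau, a linear luminance ramp, and a high
    plateau; every row is the same 1-D profile, monotone non-decreasing.
    """
    _check_lum(low_lum, high_lum)
    if low_lum > high_lum:
        raise ValueError("low_lum must not exceed high_lum")
    if not (0.0 <= ramp_width_frac < 1.0):
        raise ValueError("ramp_width_frac must lie in [0, 1)")
    _check_size(size, size)
    ramp_w = int(round(ramp_width_frac * size))
    x0 = (size - ramp_w) // 2
    profile = np.empty(size, dtype=float)
    profile[:x0] = low_lum
    if ramp_w > 0:
        # exact slope (high-low)/ramp_w between the plateau edges
        profile[x0 : x0 + ramp_w] = low_lum + (high_lum - low_lum) * (
            np.arange(ramp_w) / ramp_w
        )
    profile[x0 + ramp_w :] = high_lum
    return np.tile(profile, (size, 1))


def make_chevreul(
    size: int = 128,
    n_steps: int = 5,
    low_lum: float = 0.1,
    high_lum: float = 0.9,
) -> np.ndarray:
    """Chevreul staircase: ``n_steps`` equal-width uniform bands with
    equally spaced luminances from ``low_lum`` to ``high_lum``.
    """
    _check_lum(low_lum, high_lum)
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    _check_size(size, size)
    lums = np.linspace(low_lum, high_lum, n_steps)
    edges = np.linspace(0, size, n_steps + 1).astype(int)
    img = np.empty((size, size), dtype=float)
    for i in range(n_steps):
        img[:, edges[i] : edges[i + 1]] = lums[i]
    return img


#: Default bars drawn over the central receptive field in the dynamic
#: stimulus, variant A: (column offset from the region center, width px,
#: height px, luminance).  Two thin bright and two thin dark vertical bars,
#: vertically centered and a few receptive fields tall — finite bars leave
#: weak diagonal/horizontal energy at their ends, as in displays where the
#: bars cover only the central receptive field.
DEFAULT_BAR_SPEC: tuple[tuple[int, int, int, float], ...] = (
    (-6, 2, 16, 0.0),
    (-2, 2, 16, 1.0),
    (2, 2, 16, 1.0),
    (6, 2, 16, 0.0),
)


def make_rossi_paradiso(
    size: tuple[int, int] = (64, 96),
    variant: str = "A",
    mod_freq_hz: float = 2.0,
    tau_ms: float = 10.0,
    n_periods: int = 3,
    mean_lum: float = 0.5,
    mod_depth: float = 0.4,
    bar_spec: tuple[tuple[int, int, float], ...] = DEFAULT_BAR_SPEC,
) -> FrameSequence:
    """Dynamic flank-modulation display (Rossi & Paradiso paradigm).

    Three equally-sized vertical regions.  The two flank regions are
    modulated sinusoidally in time around ``mean_lum``; frames are sampled
    once per membrane time constant, so one modulation period spans
    P = 1/(mod_freq_hz * tau_s) frames (2 Hz with tau = 10 ms gives 50
    frames per period).

    Variant "A": central region held at ``mean_lum`` with static thin
    bright/dark vertical bars over the central receptive field.
    Variant "B": no light in the central region (luminance 0, no bars).
    """
    _check_lum(mean_lum)
    if mod_depth < 0 or mod_depth > min(mean_lum, 1.0 - mean_lum):
        raise ValueError("mod_depth must satisfy 0 <= d <= min(mean, 1-mean)")
    if variant not in ("A", "B"):
        raise ValueError("variant must be 'A' or 'B'")
    h, w = size
    _check_size(h, w)
    tau_s = tau_ms / 1000.0
    frames_per_period = 1.0 / (mod_freq_hz * tau_s)
    if frames_per_period < 8:
        raise ValueError(
            f"{frames_per_period:.1f} frames/period would alias; need >= 8"
        )
    p_int = int(round(frames_per_period))
    n_frames = int(round(n_periods * frames_per_period))
    region_w = w // 3
    center = np.full((h, w - 2 * region_w), mean_lum if variant == "A" else 0.0)
    if variant == "A":
        c_mid = center.shape[1] // 2
        r_mid = h // 2
        for off, width, height, lum in bar_spec:
            _check_lum(lum)
            c0 = c_mid + off - width // 2
            r0 = max(r_mid - height // 2, 0)
            if c0 < 0 or c0 + width > center.shape[1]:
                raise ValueError("bar_spec bar outside the central region")
            center[r0 : r0 + height, c0 : c0 + width] = lum
    frames = np.empty((n_frames, h, w), dtype=float)
    k = np.arange(n_frames)
    flank_lum = mean_lum + mod_depth * np.sin(2.0 * np.pi * k / frames_per_period)
    for i in range(n_frames):
        frames[i, :, :region_w] = flank_lum[i]
        frames[i, :, w - region_w :] = flank_lum[i]
        frames[i, :, region_w : w - region_w] = center
    return FrameSequence(
        frames,
        frame_period=1.0,
        meta={
            "variant": variant,
            "mod_freq_hz": mod_freq_hz,
            "tau_ms": tau_ms,
            "frames_per_period": p_int,
            "mean_lum": mean_lum,
            "mod_depth": mod_depth,
            "region_width": region_w,
            "flank_lum": flank_lum,
        },
    )


def make_sine_grating(
    size: int = 128,
    freq: float = 8.0,
    orientation: float = 90.0,
    mean_lum: float = 0.5,
    contrast: float = 0.4,
) -> np.ndarray:
    """Full-field sinusoidal grating.

    ``orientation`` is the angle (degrees) of the constant-phase stripes:
    0 gives horizontal stripes (luminance varying down the rows), 90 gives
    vertical stripes (luminance varying along the columns).  ``freq`` is in
    cycles per image.
    """
    _check_lum(mean_lum)
    if contrast < 0 or contrast > min(mean_lum, 1.0 - mean_lum):
        raise ValueError("contrast must satisfy 0 <= c <= min(mean, 1-mean)")
    _check_size(size, size)
    th = np.deg2rad(orientation)
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    # phase advances perpendicular to the stripes
    u = np.cos(th) * rows + np.sin(th) * cols
    return mean_lum + contrast * np.sin(2.0 * np.pi * freq * u / size)
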