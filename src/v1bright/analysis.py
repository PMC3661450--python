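"""Quantitative read-outs of model responses.

Provides brightness profiles through percept maps, phase-locking analysis
of dynamic responses against the flank-luminance modulation, per-orientation
modulation amplitudes, and the spatial-frequency gain curve of the full
static pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .percept import PerceptMap

__all__ = [
    "PhaseReport",
    "GainCurve",
    "brightness_profile",
    "phase_locking",
    "orientation_modulation",
    "frequency_gain",
    "oscillation_period",
    "cycle_aligned_mean",
]


def oscillation_period(trace: np.ndarray) -> tuple[int, float]:
    """Dominant oscillation period of a steady-state activity trace.

    Returns (lag in samples, autocorrelation at that lag) for the first
    local maximum of the normalized autocorrelation at nonzero lag; (0, 0)
    if the trace has no oscillatory structure.
    """
    from scipy.signal import find_peaks

    t = np.asarray(trace, dtype=float)
    t = t - t.mean()
    if t.std() == 0.0:
        return 0, 0.0
    ac = np.correlate(t, t, "full")[len(t) - 1 :]
    ac /= ac[0]
    peaks, _ = find_peaks(ac)
    if len(peaks) == 0:
        return 0, 0.0
    return int(peaks[0]), float(ac[peaks[0]])


def cycle_aligned_mean(trace: np.ndarray) -> float:
    """Mean of a steady-state trace over an integer number of oscillation
    cycles (falls back to the plain mean for non-oscillatory traces).
    Removes the partial-cycle sensitivity of fixed-window averages."""
    t = np.asarray(trace, dtype=float)
    period, _ = oscillation_period(t)
    if period == 0:
        return float(t.mean())
    n = (len(t) // period) * period
    return float(t[:n].mean())


def brightness_profile(
    pmap: PerceptMap | np.ndarray, axis: str = "row", index: int | None = None
) -> np.ndarray:
    """Extract a 1-D brightness profile (a single row or column).

    ``axis`` selects whether ``index`` names a row (profile runs along the
    columns) or a column; ``index`` defaults to the central one.
    """
    pixels = pmap.pixels if isinstance(pmap, PerceptMap) else np.asarray(pmap)
    if axis not in ("row", "col"):
        raise ValueError("axis must be 'row' or 'col'")
    if axis == "row":
        idx = pixels.shape[0] // 2 if index is None else index
        return np.array(pixels[idx, :])
    idx = pixels.shape[1] // 2 if index is None else index
    return np.array(pixels[:, idx])


@dataclass
class PhaseReport:
    """Amplitude and phase of a response at the flank modulation frequency.

    ``phase_diff`` (radians, in (-pi, pi]) is measured against the flank
    luminance sinusoid sin(2*pi*i/period); antiphase responses report
    values near +/- pi.  ``smoothed`` is the series after convolution with
    a square window one modulation period wide (display/diagnostic form of
    the analysis; amplitude and phase are estimated by sinusoidal
    projection of the raw series over an integer number of periods).
    """

    mod_freq: float
    amplitude: float
    phase_diff: float
    smoothed: np.ndarray


def phase_locking(
    series: np.ndarray,
    period: float,
    discard: int = 0,
    mod_freq: float | None = None,
) -> PhaseReport:
    """Phase-lock a response series to the flank modulation.

    Parameters
    ----------
    series : samples aligned with the stimulus such that sample ``i``
        (after ``discard``) corresponds to flank phase 2*pi*i/period.
        With frame-rate sampling at one frame per membrane time constant,
        ``period`` is the frames-per-period of the stimulus.
    period : modulation period in samples.
    discard : leading samples dropped as transient.
    mod_freq : optional physical frequency (Hz) recorded in the report.
    """
    s = np.asarray(series, dtype=float)[discard:]
    n_per = int(len(s) // period)
    if n_per < 3:
        raise ValueError(
            f"series covers {n_per} modulation periods after discard; need >= 3"
        )
    n_use = int(round(n_per * period))
    sc = s[:n_use] - s[:n_use].mean()
    i = np.arange(n_use)
    z = np.sum(sc * np.exp(-2j * np.pi * i / period))
    amplitude = 2.0 * np.abs(z) / n_use
    # z has the phase of the cosine component; the sin reference lags pi/2
    phase = np.angle(z) + np.pi / 2.0
    phase_diff = (phase + np.pi) % (2.0 * np.pi) - np.pi
    if phase_diff == -np.pi:
        phase_diff = np.pi
    win = max(int(round(period)), 1)
    smoothed = np.convolve(s, np.ones(win) / win, mode="same")
    return PhaseReport(
        mod_freq=float(mod_freq) if mod_freq is not None else 1.0 / period,
        amplitude=float(amplitude),
        phase_diff=float(phase_diff),
        smoothed=smoothed,
    )


def orientation_series(probe_series: np.ndarray) -> np.ndarray:
    """Collapse a probe recording (T, 2, n_orient, rows, cols) from
    :func:`v1bright.network.run_dynamic` into one mean time series per
    orientation, shape (n_orient, T)."""
    arr = np.asarray(probe_series, dtype=float)
    return arr.mean(axis=(1, 3, 4)).T


def orientation_modulation(
    series_per_orientation: np.ndarray,
    period: float,
    discard: int = 0,
) -> np.ndarray:
    """Modulation amplitude at the flank frequency for each orientation.

    ``series_per_orientation`` has shape (n_orientations, T); returns the
    phase-locking amplitude of each row.
    """
    arr = np.atleast_2d(np.asarray(series_per_orientation, dtype=float))
    return np.array(
        [phase_locking(row, period, discard).amplitude for row in arr]
    )


@dataclass
class GainCurve:
    """Output/input amplitude gain across spatial frequency.

    ``slope`` is the ordinary-least-squares slope of log10(gain) against
    log10(freq); a positive value means higher spatial frequencies are
    relatively amplified (shallow low-frequency fall-off of the
    high-contrast contrast-sensitivity function).
    """

    freqs: np.ndarray
    gains: np.ndarray
    slope: float
    r2: float


def _fit_loglog(freqs: np.ndarray, gains: np.ndarray) -> tuple[float, float]:
    lx = np.log10(freqs)
    ly = np.log10(gains)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


def grating_amplitude(image: np.ndarray, freq: int, axis: int = 1) -> float:
    """Amplitude of the sinusoidal component at ``freq`` cycles/image along
    ``axis``, averaged over the other axis (FFT projection)."""
    spec = np.fft.fft(np.asarray(image, dtype=float), axis=axis)
    comp = np.take(spec, int(freq), axis=axis).mean()
    return float(2.0 * np.abs(comp) / image.shape[axis])


def frequency_gain(
    params=None,
    n_scales: int = 4,
    size: int = 128,
    freqs: np.ndarray | None = None,
    contrast: float = 0.4,
    mean_lum: float = 0.5,
    disable_lateral: bool = False,
) -> GainCurve:
    """Contrast gain of the full static pipeline across spatial frequency.

    For each probed frequency (by default one per wavelet passband, at the
    band's peak) a full-field vertical-stripe sinusoidal grating is run
    through decomposition, rectification, the recurrent network and percept
    reconstruction; the gain is the amplitude of the percept's component at
    the input frequency divided by the stimulus amplitude.  Full-field
    gratings are spatially periodic, so the pipeline runs under the exact
    "wrap" boundary rule.

    With ``disable_lateral`` the contextual connections J and W are zeroed
    in both numerator and baseline runs, so the modulation ratio is
    identically 1 and the gain curve is flat at 1 (slope 0) up to clipping
    effects — the control for the lateral origin of the gain slope.
    """
    # local import: pipeline imports this module's GainCurve consumers
    from .network import ModelParams, build_connectivity, run_static
    from .percept import percept_static
    from .stimuli import make_sine_grating
    from .wavelet import decompose, rectify_normalize, scale_peak_freq
    from dataclasses import replace as _replace

    params = ModelParams() if params is None else params
    params = _replace(params, boundary="wrap")
    if freqs is None:
        freqs = np.array(
            [round(scale_peak_freq(s, size)) for s in range(1, n_scales + 1)],
            dtype=float,
        )
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) < 3:
        raise ValueError("need >= 3 frequencies for a slope")
    kernel = build_connectivity(params, n_scales=n_scales)
    if disable_lateral:
        kernel.J = np.zeros_like(kernel.J)
        kernel.W = np.zeros_like(kernel.W)
        kernel.j_tables = {k: np.zeros_like(v) for k, v in kernel.j_tables.items()}
        kernel.w_tables = {k: np.zeros_like(v) for k, v in kernel.w_tables.items()}
    gains = []
    for f in freqs:
        stim = make_sine_grating(
            size=size, freq=f, orientation=90.0, mean_lum=mean_lum, contrast=contrast
        )
        pyr = decompose(stim, n_scales=n_scales, boundary="wrap")
        drive = rectify_normalize(pyr, params.norm_lo, params.norm_hi)
        resp = run_static(drive, kernel, params)
        pmap = percept_static(pyr, resp.alpha, resp.alpha0)
        amp = grating_amplitude(pmap.pixels, int(f), axis=1)
        if amp <= 0.0:
            raise ValueError(f"degenerate zero output amplitude at f={f}")
        gains.append(amp / contrast)
    gains = np.array(gains)
    slope, r2 = _fit_loglog(freqs, gains)
    return GainCurve(freqs=freqs, gains=gains, slope=slope, r2=r2)
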