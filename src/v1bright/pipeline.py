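"""End-to-end drivers tying front-end, network and reconstruction together."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    ModelParams,
    ConnectivityKernel,
    StaticResponse,
    DynamicResponse,
    build_connectivity,
    run_static,
    run_dynamic,
)
from .percept import PerceptMap, percept_static, percept_dynamic
from .stimuli import FrameSequence
from .wavelet import WaveletPyramid, decompose, rectify_normalize, max_scales

__all__ = ["StaticRun", "DynamicRun", "static_pipeline", "dynamic_pipeline"]


@dataclass
class StaticRun:
    """Everything computed for one static stimulus."""

    stimulus: np.ndarray
    pyramid: WaveletPyramid
    response: StaticResponse
    percept: PerceptMap
    params: ModelParams
    n_scales: int


@dataclass
class DynamicRun:
    """Everything computed for one stimulus sequence."""

    sequence: FrameSequence
    pyramids: list[WaveletPyramid]
    response: DynamicResponse
    response0: DynamicResponse
    percepts: list[PerceptMap] = field(repr=False)
    params: ModelParams = None
    n_scales: int = 0

    def brightness_series(self, cols: slice, rows: slice = slice(None)) -> np.ndarray:
        """Mean perceived brightness of a region, one sample per frame."""
        return np.array([p.pixels[rows, cols].mean() for p in self.percepts])

    def central_brightness_series(self, frac: float = 0.5) -> np.ndarray:
        """Mean perceived brightness of the central window of the display
        (a ``frac`` share of the middle region, centered), one sample per
        frame — the region the physiological recordings probe."""
        w = self.sequence.shape[1]
        rw = self.sequence.meta.get("region_width", w // 3)
        half = max(int(round(rw * frac / 2)), 1)
        return self.brightness_series(cols=slice(w // 2 - half, w // 2 + half))


def _resolve_scales(shape: tuple[int, int], n_scales: int | None) -> int:
    cap = max_scales(shape)
    return min(4, cap) if n_scales is None else n_scales


def static_pipeline(
    image: np.ndarray,
    params: ModelParams | None = None,
    n_scales: int | None = None,
    kernel: ConnectivityKernel | None = None,
) -> StaticRun:
    """Run the full static pathway: decompose, rectify/normalize, simulate
    to the oscillatory steady state, and reconstruct the percept."""
    params = ModelParams() if params is None else params
    image = np.asarray(image, dtype=float)
    n_scales = _resolve_scales(image.shape, n_scales)
    pyr = decompose(image, n_scales=n_scales, boundary=params.boundary)
    drive = rectify_normalize(pyr, params.norm_lo, params.norm_hi)
    if kernel is None:
        kernel = build_connectivity(params, n_scales=n_scales)
    resp = run_static(drive, kernel, params)
    pmap = percept_static(
        pyr,
        resp.alpha,
        resp.alpha0,
        provenance={"params": params.to_dict(), "n_scales": n_scales},
    )
    return StaticRun(
        stimulus=image,
        pyramid=pyr,
        response=resp,
        percept=pmap,
        params=params,
        n_scales=n_scales,
    )


def dynamic_pipeline(
    sequence: FrameSequence,
    params: ModelParams | None = None,
    n_scales: int | None = None,
    kernel: ConnectivityKernel | None = None,
    probe: tuple | None = None,
) -> DynamicRun:
    """Run the full dynamic pathway.

    Frames are decomposed individually, normalized jointly over all frames,
    simulated with the drive advancing one frame per membrane time constant,
    and reconstructed per frame from the instantaneous excitatory output
    (baseline: identical run with lateral connections disabled).
    """
    params = ModelParams() if params is None else params
    n_scales = _resolve_scales(sequence.shape, n_scales)
    pyrs = [
        decompose(fr, n_scales=n_scales, boundary=params.boundary)
        for fr in sequence.frames
    ]
    drive = rectify_normalize(pyrs, params.norm_lo, params.norm_hi)
    if kernel is None:
        kernel = build_connectivity(params, n_scales=n_scales)
    resp = run_dynamic(
        drive, kernel, params, frame_period=sequence.frame_period, probe=probe
    )
    resp0 = run_dynamic(
        drive,
        kernel,
        params,
        frame_period=sequence.frame_period,
        probe=probe,
        disable_lateral=True,
    )
    percepts = percept_dynamic(pyrs, resp.gx_frames, resp0.gx_frames)
    return DynamicRun(
        sequence=sequence,
        pyramids=pyrs,
        response=resp,
        response0=resp0,
        percepts=percepts,
        params=params,
        n_scales=n_scales,
    )
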