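"""Perceived-brightness reconstruction.

The network's averaged excitatory output acts as a weighting function of
the wavelet coefficients: each coefficient is scaled by the contextual
modulation ratio

    r = (eps + alpha) / (eps + alpha0)

of its matching polarity channel, where alpha is the activity with the
full lateral connectivity and alpha0 the context-free baseline (lateral
connections disabled).  The ratio reduces to 1 wherever context leaves
activity unchanged, so an uncontextualized stimulus is reproduced exactly
(the residual plane is never reweighted, anchoring mean luminance).  The
reweighted pyramid is inverted with the exact additive inverse transform.
Percept values are deliberately NOT re-clipped to [0, 1]: over- and
undershoots are the predicted brightness illusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wavelet import WaveletPyramid, reconstruct

__all__ = ["PerceptMap", "modulation_ratio", "percept_static", "percept_dynamic"]

EPS = 1e-6
R_MIN = 0.25
R_MAX = 4.0


@dataclass
class PerceptMap:
    """A reconstructed perceived-brightness image."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def modulation_ratio(
    alpha: np.ndarray,
    alpha0: np.ndarray,
    eps: float = EPS,
    r_min: float = R_MIN,
    r_max: float = R_MAX,
) -> np.ndarray:
    """Clipped contextual modulation ratio (eps + alpha) / (eps + alpha0)."""
    return np.clip((eps + alpha) / (eps + alpha0), r_min, r_max)


def _reweight(planes: np.ndarray, ratio: np.ndarray) -> np.ndarray:
    """Apply ON/OFF ratios to signed coefficients.

    ``ratio`` has shape (2, S, O, H, W); channel 0 scales positive
    coefficients, channel 1 negative ones.
    """
    return ratio[0] * np.maximum(planes, 0.0) - ratio[1] * np.maximum(-planes, 0.0)


def percept_static(
    pyramid: WaveletPyramid,
    alpha: np.ndarray,
    alpha0: np.ndarray,
    eps: float = EPS,
    r_min: float = R_MIN,
    r_max: float = R_MAX,
    provenance: dict | None = None,
) -> PerceptMap:
    """Perceived brightness of a static stimulus.

    ``alpha``/``alpha0`` are the averaged outputs of
    :func:`v1bright.network.run_static` with shape (2, S, O, H, W) matching
    the pyramid's planes.
    """
    if alpha.shape != (2,) + pyramid.planes.shape or alpha0.shape != alpha.shape:
        raise ValueError(
            f"alpha shape {alpha.shape} does not match pyramid planes "
            f"{(2,) + pyramid.planes.shape}"
        )
    ratio = modulation_ratio(alpha, alpha0, eps, r_min, r_max)
    new_planes = _reweight(pyramid.planes, ratio)
    pixels = reconstruct(
        WaveletPyramid(planes=new_planes, residual=pyramid.residual)
    )
    return PerceptMap(pixels=pixels, provenance=provenance or {})


def percept_dynamic(
    pyramid_seq: list[WaveletPyramid],
    gx_frames: np.ndarray,
    gx0_frames: np.ndarray,
    eps: float = EPS,
    r_min: float = R_MIN,
    r_max: float = R_MAX,
) -> list[PerceptMap]:
    """Perceived brightness for a stimulus sequence.

    Same reweighting rule as the static case, but per frame, using the
    instantaneous excitatory output (no temporal averaging); the baseline
    is the per-frame output of the lateral-free run.
    """
    if len(pyramid_seq) != gx_frames.shape[0] or gx0_frames.shape != gx_frames.shape:
        raise ValueError("pyramid_seq / gx_frames / gx0_frames lengths differ")
    out = []
    for f, pyr in enumerate(pyramid_seq):
        out.append(
            percept_static(
                pyr,
                gx_frames[f].astype(np.float64),
                gx0_frames[f].astype(np.float64),
                eps,
                r_min,
                r_max,
                provenance={"frame": f},
            )
        )
    return out
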