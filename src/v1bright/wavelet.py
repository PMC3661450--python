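"""Undecimated oriented wavelet front-end.

The decomposition is an additive a trous scheme: the image is repeatedly
smoothed with a holed cubic B-spline kernel [1,4,6,4,1]/16 (hole spacing
2**(s-1) at level s) and the detail at each scale is the difference of
successive smoothings.  Each isotropic detail plane is split exactly into
four oriented planes (horizontal, 45 deg, vertical, 135 deg) using the
separable structure of the 2-D smoothing:

    1 - SrSc = (1-Sr)Sc  +  Sr(1-Sc)  +  (1-Sr)(1-Sc)
               horizontal    vertical      doubly high-pass D

where Sr / Sc smooth along rows-axis / columns-axis.  D is split into the
two diagonal planes with diagonally holed smoothings S11 and S1m1:

    d45  = (D + S11 D - S1m1 D) / 2
    d135 = (D - S11 D + S1m1 D) / 2

so d45 + d135 = D exactly and horizontal mirroring swaps the two diagonal
planes.  The sum of all oriented planes plus the residual therefore
reconstructs the input to machine precision, which is what lets network
activity be folded back into a perceived-brightness image.

Orientation index convention (shared with the cortical network):
0 = horizontal features, 1 = 45 deg diagonal, 2 = vertical, 3 = 135 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "WaveletPyramid",
    "RectifiedDrive",
    "ORIENTATIONS",
    "decompose",
    "reconstruct",
    "rectify_normalize",
    "max_scales",
    "scale_peak_freq",
]

ORIENTATIONS = ("horizontal", "diagonal1", "vertical", "diagonal2")
N_ORIENT = 4

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

_BOUNDARY_MODES = {"mirror": "reflect", "wrap": "wrap"}


@dataclass
class WaveletPyramid:
    """Full-resolution oriented multiscale coefficients plus residual.

    ``planes`` has shape (n_scales, 4, H, W); scale index 0 is the finest
    band.  Summing every plane with the residual recovers the decomposed
    image exactly.
    """

    planes: np.ndarray
    residual: np.ndarray
    boundary: str = "mirror"

    @property
    def n_scales(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.residual.shape


@dataclass
class RectifiedDrive:
    """ON/OFF half-wave-rectified, globally normalized network input.

    ``data`` has shape (2, n_scales, 4, H, W) for a static stimulus or
    (n_frames, 2, n_scales, 4, H, W) for a sequence; channel 0 is ON
    (positive coefficients), channel 1 is OFF.  Nonzero magnitudes are
    mapped affinely into (norm_lo, norm_hi]; coefficients at the global
    minimum (zero) stay exactly zero.
    """

    data: np.ndarray
    norm_lo: float
    norm_hi: float

    @property
    def is_sequence(self) -> bool:
        return self.data.ndim == 6


def max_scales(shape: tuple[int, int]) -> int:
    """Largest admissible number of scales for an image shape."""
    return int(np.floor(np.log2(min(shape)))) - 1


def _smooth1d(img: np.ndarray, axis: int, spacing: int, mode: str) -> np.ndarray:
    """Convolve with the holed B3 kernel along one axis."""
    kernel = np.zeros(4 * spacing + 1)
    kernel[::spacing] = _B3
    return ndimage.correlate1d(img, kernel, axis=axis, mode=mode)


def _smooth_diag(img: np.ndarray, spacing: int, sign: int, mode: str) -> np.ndarray:
    """Convolve with the holed B3 kernel along a diagonal direction.

    ``sign`` +1 smooths along the (down-right) main diagonal, -1 along the
    anti-diagonal.
    """
    size = 4 * spacing + 1
    kernel = np.zeros((size, size))
    idx = np.arange(5) * spacing
    if sign > 0:
        kernel[idx, idx] = _B3
    else:
        kernel[idx, size - 1 - idx] = _B3
    return ndimage.correlate(img, kernel, mode=mode)


def decompose(image: np.ndarray, n_scales: int = 4, boundary: str = "mirror") -> WaveletPyramid:
    """Undecimated oriented a trous decomposition.

    Parameters
    ----------
    image : 2-D luminance array.
    n_scales : number of dyadic detail levels; must not exceed
        ``max_scales(image.shape)``.
    boundary : "mirror" (default) or "wrap" extension.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if n_scales < 1 or n_scales > max_scales(image.shape):
        raise ValueError(
            f"n_scales={n_scales} invalid for shape {image.shape} "
            f"(max {max_scales(image.shape)})"
        )
    mode = _BOUNDARY_MODES[boundary]
    h, w = image.shape
    planes = np.empty((n_scales, N_ORIENT, h, w))
    c = image
    for s in range(n_scales):
        spacing = 2**s
        cr = _smooth1d(c, 0, spacing, mode)   # smoothed along rows-axis
        cc = _smooth1d(c, 1, spacing, mode)   # smoothed along cols-axis
        crc = _smooth1d(cr, 1, spacing, mode)
        horiz = cc - crc          # (1-Sr)Sc c : high-pass down the rows
        vert = cr - crc           # Sr(1-Sc) c : high-pass along the cols
        diag = c - cr - cc + crc  # (1-Sr)(1-Sc) c
        d_main = _smooth_diag(diag, spacing, +1, mode)
        d_anti = _smooth_diag(diag, spacing, -1, mode)
        planes[s, 0] = horiz
        planes[s, 1] = 0.5 * (diag + d_main - d_anti)
        planes[s, 2] = vert
        planes[s, 3] = 0.5 * (diag - d_main + d_anti)
        c = crc
    return WaveletPyramid(planes=planes, residual=c, boundary=boundary)


def reconstruct(pyramid: WaveletPyramid) -> np.ndarray:
    """Exact additive inverse: sum of all oriented planes plus residual."""
    return pyramid.planes.sum(axis=(0, 1)) + pyramid.residual


def scale_peak_freq(scale: int, size: int) -> float:
    """Peak spatial frequency (cycles/image) of a detail band.

    The level-s band-pass transfer function along one axis is
    prod_{j<s} B(2^j f) - prod_{j<=s} B(2^j f) with B the B3-spline DFT;
    its maximum is located numerically.  ``scale`` is 1-based.  The search
    is capped at 0.45*size to keep probe gratings clear of the Nyquist
    sampling degeneracy (a sine at exactly size/2 cycles vanishes on the
    integer pixel grid).
    """
    f = np.linspace(0.5, 0.45 * size, 2048)
    om = 2.0 * np.pi * f / size

    def b3(x: np.ndarray) -> np.ndarray:
        return (6 + 8 * np.cos(x) + 2 * np.cos(2 * x)) / 16.0

    lo = np.ones_like(om)
    for j in range(scale - 1):
        lo = lo * b3(2**j * om)
    hi = lo * b3(2 ** (scale - 1) * om)
    return float(f[np.argmax(np.abs(lo - hi))])


def rectify_normalize(
    pyramids: WaveletPyramid | list[WaveletPyramid],
    norm_lo: float = 1.0,
    norm_hi: float = 3.0,
) -> RectifiedDrive:
    """Half-wave rectify coefficients into ON/OFF channels and normalize.

    A single affine map, computed from the minimum and maximum rectified
    magnitude over all positions, scales, orientations, polarities (and all
    frames for a sequence), sends magnitudes into [norm_lo, norm_hi];
    magnitudes at the global minimum (the rectification zeros) are then
    set back to exactly 0, so silent units receive no input.  An all-zero
    pyramid yields an all-zero drive.
    """
    seq = isinstance(pyramids, (list, tuple))
    plist = list(pyramids) if seq else [pyramids]
    coeffs = np.stack([p.planes for p in plist])  # (F, S, O, H, W)
    on = np.maximum(coeffs, 0.0)
    off = np.maximum(-coeffs, 0.0)
    data = np.stack([on, off], axis=1)  # (F, 2, S, O, H, W)
    vmax = data.max()
    vmin = data.min()  # 0 whenever any coefficient is zero or sign-split
    if vmax <= vmin:
        out = np.zeros_like(data)
    else:
        out = norm_lo + (norm_hi - norm_lo) * (data - vmin) / (vmax - vmin)
        # magnitudes at (or within float round-off of) the global minimum
        # are silent units, not weak drives
        out[data <= vmin + 1e-12 * (vmax - vmin)] = 0.0
    if not seq:
        out = out[0]
    return RectifiedDrive(data=out, norm_lo=norm_lo, norm_hi=norm_hi)
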