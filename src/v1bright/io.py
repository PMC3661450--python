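"""Writers for stimuli, pyramids, responses and analysis tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
import tifffile

from .stimuli import FrameSequence
from .wavelet import WaveletPyramid, ORIENTATIONS
from .analysis import PhaseReport, GainCurve

__all__ = [
    "write_png",
    "write_tiff",
    "write_sequence",
    "write_pyramid",
    "write_profile_csv",
    "write_phase_report",
    "write_gain_curve",
    "read_image",
]


def write_png(path: str | Path, image: np.ndarray) -> Path:
    """8-bit PNG; values clipped to [0, 1]."""
    path = Path(path)
    data = (np.clip(image, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    iio.imwrite(path, data, extension=".png")
    return path


def write_tiff(path: str | Path, image: np.ndarray) -> Path:
    """16-bit TIFF; values clipped to [0, 1]."""
    path = Path(path)
    data = (np.clip(image, 0.0, 1.0) * 65535.0).round().astype(np.uint16)
    tifffile.imwrite(path, data)
    return path


def write_sequence(directory: str | Path, seq: FrameSequence, stem: str = "frame") -> Path:
    """Numbered 8-bit PNG frames plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(seq.frames):
        name = f"{stem}_{i:04d}.png"
        write_png(directory / name, frame)
        names.append(name)
    meta = {k: v for k, v in seq.meta.items() if not isinstance(v, np.ndarray)}
    manifest = {
        "frame_period_tau": seq.frame_period,
        "n_frames": seq.n_frames,
        "frames": names,
        **meta,
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def write_pyramid(directory: str | Path, pyr: WaveletPyramid) -> Path:
    """One float TIFF per plane plus residual, with a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in range(pyr.n_scales):
        for o, oname in enumerate(ORIENTATIONS):
            name = f"plane_s{s + 1}_{oname}.tiff"
            tifffile.imwrite(directory / name, pyr.planes[s, o].astype(np.float32))
            entries.append({"file": name, "scale": s + 1, "orientation": oname})
    tifffile.imwrite(directory / "residual.tiff", pyr.residual.astype(np.float32))
    manifest = {
        "n_scales": pyr.n_scales,
        "boundary": pyr.boundary,
        "planes": entries,
        "residual": "residual.tiff",
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def write_profile_csv(path: str | Path, **profiles: np.ndarray) -> Path:
    """Named 1-D profiles as CSV columns."""
    path = Path(path)
    pd.DataFrame({k: np.asarray(v) for k, v in profiles.items()}).to_csv(
        path, index_label="position"
    )
    return path


def write_phase_report(path: str | Path, report: PhaseReport) -> Path:
    path = Path(path)
    payload = {
        "mod_freq": report.mod_freq,
        "amplitude": report.amplitude,
        "phase_diff_rad": report.phase_diff,
        "smoothed": list(map(float, report.smoothed)),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def write_gain_curve(path: str | Path, curve: GainCurve) -> Path:
    path = Path(path)
    df = pd.DataFrame({"freq_cpi": curve.freqs, "gain": curve.gains})
    df.attrs["slope"] = curve.slope
    df.to_csv(path, index=False)
    meta = Path(str(path) + ".json")
    meta.write_text(json.dumps({"slope": curve.slope, "r2": curve.r2}, indent=2))
    return path


def write_panel(path: str | Path, stimulus: np.ndarray,
                percept: np.ndarray, gap: int = 4) -> Path:
    """Side-by-side stimulus/percept comparison as an 8-bit PNG."""
    h, w = stimulus.shape
    panel = np.ones((h, 2 * w + gap))
    panel[:, :w] = np.clip(stimulus, 0.0, 1.0)
    panel[:, w + gap :] = np.clip(percept, 0.0, 1.0)
    return write_png(path, panel)


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale luminance image scaled to [0, 1]."""
    arr = np.asarray(iio.imread(path)).astype(float)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    peak = 65535.0 if arr.max() > 255 else 255.0
    return arr / peak
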