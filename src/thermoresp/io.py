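"""Frame, signal and transform I/O.

Thermal frames travel as 16-bit TIFF stacks quantised to 0.01 degC (the
scale/offset and frame rate ride in the TIFF description as JSON) or as
float NPZ; visible frames as PNG sequences.  Signals, RR series and ROI
logs are plain CSV; affine maps are JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from numpy.typing import NDArray

from .errors import ConfigError, ThermorespError
from .registration import AffineMap
from .resp_signal import RespSignal, RRWindow
from .roi_tracking import TDRecord

__all__ = [
    "ArrayRGBTSequence",
    "read_frames",
    "write_thermal_tiff",
    "write_rgb_pngs",
    "write_npz",
    "save_affine",
    "load_affine",
    "rr_to_csv",
    "rr_from_csv",
    "signal_to_csv",
    "signal_from_csv",
    "roi_log_to_csv",
]


class ArrayRGBTSequence:
    """In-memory paired frame streams (file-backed recordings)."""

    def __init__(self, rgb_frames: Sequence[NDArray],
                 thermal_frames: Sequence[NDArray], fps: float):
        if len(rgb_frames) != len(thermal_frames):
            raise ThermorespError(
                f"stream length mismatch: {len(rgb_frames)} visible vs "
                f"{len(thermal_frames)} thermal frames")
        self._rgb = rgb_frames
        self._thermal = thermal_frames
        self.fps = float(fps)
        self.n_frames = len(rgb_frames)
        self.rgb_shape = np.shape(rgb_frames[0])[:2]
        self.thermal_shape = np.shape(thermal_frames[0])[:2]

    def rgb_frame(self, i: int) -> NDArray:
        return self._rgb[i]

    def thermal_frame(self, i: int) -> NDArray:
        return self._thermal[i]

    def iter_rgb(self):
        return iter(self._rgb)

    def iter_thermal(self):
        return iter(self._thermal)


def _parse_tiff_meta(tif: tifffile.TiffFile) -> dict:
    desc = tif.pages[0].description
    if desc:
        try:
            meta = json.loads(desc)
            if isinstance(meta, dict):
                return meta
        except (json.JSONDecodeError, TypeError):
            pass
    return {}


def read_frames(path: str | Path, modality: str = "thermal",
                ) -> tuple[list[NDArray], float | None]:
    """Read a frame sequence from a TIFF stack, NPZ file, or directory.

    Directories must hold numbered .png/.tif frames with a contiguous
    index; a gap raises an error naming the missing index.  16-bit
    thermal TIFFs carrying scale/offset metadata are converted to degC.
    Returns ``(frames, fps_or_None)``.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise ThermorespError(f"no frame files in {path}")
        indices = []
        for p in files:
            m = re.search(r"(\d+)", p.stem)
            if not m:
                raise ThermorespError(f"cannot parse frame index from {p.name}")
            indices.append(int(m.group(1)))
        lo = min(indices)
        expected = set(range(lo, lo + len(indices)))
        missing = sorted(expected - set(indices))
        if missing:
            raise ThermorespError(f"missing frame index {missing[0]} in {path}")
        order = np.argsort(indices)
        frames = [np.asarray(iio.imread(files[i])) for i in order]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ThermorespError(f"mixed frame shapes in {path}: {shapes}")
        return frames, None
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            meta = _parse_tiff_meta(tif)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [f for f in stack]
        if "scale" in meta:
            scale = float(meta["scale"])
            offset = float(meta.get("offset", 0.0))
            frames = [f.astype(np.float64) * scale + offset for f in frames]
        return frames, meta.get("fps")
    if path.suffix.lower() == ".npz":
        data = np.load(path)
        frames = [f for f in data["frames"]]
        fps = float(data["fps"]) if "fps" in data else None
        return frames, fps
    raise ThermorespError(f"unsupported frame container: {path}")


def write_thermal_tiff(path: str | Path, frames: Sequence[NDArray],
                       fps: float, scale: float = 0.01,
                       offset: float = 0.0) -> None:
    """Write degC frames as a 16-bit TIFF stack quantised to ``scale``."""
    stack = np.stack([np.asarray(f, dtype=np.float64) for f in frames])
    quant = np.round((stack - offset) / scale)
    if quant.min() < 0 or quant.max() > np.iinfo(np.uint16).max:
        raise ThermorespError("temperature range does not fit 16-bit "
                              f"quantisation with offset {offset}")
    meta = json.dumps({"scale": scale, "offset": offset, "fps": fps})
    tifffile.imwrite(path, quant.astype(np.uint16), description=meta,
                     photometric="minisblack")


def write_rgb_pngs(directory: str | Path, frames: Sequence[NDArray]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(directory / f"frame_{i:06d}.png",
                    np.asarray(frame, dtype=np.uint8))


def write_npz(path: str | Path, frames: Sequence[NDArray], fps: float) -> None:
    np.savez_compressed(path, frames=np.stack(frames), fps=fps)


def export_feature_maps_tiff(path: str | Path, pc, moments=None) -> None:
    """Write PC maps (and optionally moment maps) as a float32 multi-page
    TIFF for visual inspection: one page per orientation, then M and m."""
    pages = [np.asarray(p, dtype=np.float32) for p in pc.pc_per_orientation]
    if moments is not None:
        pages += [np.asarray(moments.M, dtype=np.float32),
                  np.asarray(moments.m, dtype=np.float32)]
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")


def save_affine(path: str | Path, amap: AffineMap) -> None:
    Path(path).write_text(json.dumps(amap.to_dict(), indent=2))


def load_affine(path: str | Path) -> AffineMap:
    return AffineMap.from_dict(json.loads(Path(path).read_text()))


def rr_to_csv(path: str | Path, windows: Sequence[RRWindow]) -> None:
    pd.DataFrame([{
        "window_start": w.window_start, "window_end": w.window_end,
        "rr_bpm": w.rr_bpm, "peak_freq_hz": w.peak_freq_hz,
        "spectral_peak_ratio": w.spectral_peak_ratio,
        "low_quality": w.low_quality,
    } for w in windows]).to_csv(path, index=False)


def rr_from_csv(path: str | Path) -> list[RRWindow]:
    df = pd.read_csv(path)
    return [RRWindow(window_start=float(r.window_start),
                     window_end=float(r.window_end),
                     rr_bpm=float(r.rr_bpm),
                     peak_freq_hz=float(getattr(r, "peak_freq_hz", r.rr_bpm / 60)),
                     spectral_peak_ratio=float(getattr(r, "spectral_peak_ratio", 0.0)),
                     low_quality=bool(getattr(r, "low_quality", False)))
            for r in df.itertuples()]


def signal_to_csv(path: str | Path, signal: RespSignal) -> None:
    t = signal.t0 + np.arange(len(signal)) / signal.fs
    pd.DataFrame({"time_s": t, "value": signal.values,
                  "valid": signal.valid}).to_csv(path, index=False)


def signal_from_csv(path: str | Path, fs: float | None = None) -> RespSignal:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if fs is None:
        if len(t) < 2:
            raise ThermorespError("cannot infer sampling rate from one sample")
        fs = 1.0 / float(np.median(np.diff(t)))
    valid = df["valid"].to_numpy(dtype=bool) if "valid" in df else None
    return RespSignal(values=df["value"].to_numpy(dtype=float), fs=fs,
                      valid=valid, t0=float(t[0]) if len(t) else 0.0)


def roi_log_to_csv(path: str | Path, log: Sequence[TDRecord]) -> None:
    from .roi_tracking import td_log_frame

    td_log_frame(list(log)).to_csv(path, index=False)
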