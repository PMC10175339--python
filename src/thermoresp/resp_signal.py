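"""Respiratory-signal extraction and sliding-window rate estimation.

The raw respiratory signal is the per-frame mean thermal intensity over
the mapped nostril ROI: exhaled air is warmer than inhaled air, so the
mean patch temperature oscillates at the breathing frequency.  The raw
trace is conditioned by z-scoring, a Hampel despiking filter, a short
moving average and a 2nd-order zero-phase Butterworth bandpass
restricted to the physiological band ([0.1, 0.85] Hz for adults,
[0.5, 1.5] Hz for neonates).  The rate is read off per 30 s window
(20 s slide) as 60 times the peak frequency of a chirp-Z spectrum
zoomed into the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy import signal as sps

from .errors import FlatSignalError, SignalTooShortError, ThermorespError
from .roi_tracking import ROIBox

__all__ = [
    "RespSignal",
    "BandConfig",
    "RRWindow",
    "extract_raw_signal",
    "normalize",
    "hampel_filter",
    "moving_average",
    "bandpass",
    "estimate_rr_czt",
    "filter_chain",
    "sliding_rr",
]

FloatArray = NDArray[np.floating]


@dataclass(frozen=True)
class RespSignal:
    """Per-frame scalar series with sampling rate and validity flags."""

    values: FloatArray
    fs: float
    valid: NDArray[np.bool_] | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.valid is None:
            object.__setattr__(self, "valid", np.ones(len(values), dtype=bool))
        else:
            flags = np.asarray(self.valid, dtype=bool)
            if len(flags) != len(values):
                raise ValueError("valid flags must match values in length")
            object.__setattr__(self, "valid", flags)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    def with_values(self, values: FloatArray) -> "RespSignal":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class BandConfig:
    """Physiological breathing band and bandpass filter order."""

    low_hz: float
    high_hz: float
    order: int = 2
    population: str = "custom"

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")

    @classmethod
    def adult(cls) -> "BandConfig":
        return cls(low_hz=0.1, high_hz=0.85, order=2, population="adult")

    @classmethod
    def neonate(cls) -> "BandConfig":
        return cls(low_hz=0.5, high_hz=1.5, order=2, population="neonate")

    @classmethod
    def for_population(cls, population: str) -> "BandConfig":
        try:
            return {"adult": cls.adult, "neonate": cls.neonate}[population]()
        except KeyError:
            raise ValueError(f"unknown population {population!r}") from None


@dataclass(frozen=True)
class RRWindow:
    """One sliding-window respiratory-rate estimate."""

    window_start: float     # seconds
    window_end: float
    rr_bpm: float
    peak_freq_hz: float
    spectral_peak_ratio: float
    low_quality: bool = False


def extract_raw_signal(thermal_frames: Iterable[FloatArray],
                       mapped_rois: Sequence[ROIBox | None],
                       fs: float, t0: float = 0.0) -> RespSignal:
    """Mean mapped-ROI intensity per frame, with linear gap filling.

    Frames without a (valid) ROI are flagged invalid and interpolated
    linearly between neighbouring valid samples; runs at either edge are
    held at the nearest valid value.
    """
    values: list[float] = []
    flags: list[bool] = []
    n_frames = 0
    for i, frame in enumerate(thermal_frames):
        n_frames += 1
        roi = mapped_rois[i] if i < len(mapped_rois) else None
        if roi is not None and roi.valid:
            patch = np.asarray(frame)[roi.slices()]
            values.append(float(patch.mean()))
            flags.append(True)
        else:
            values.append(np.nan)
            flags.append(False)
    if n_frames != len(mapped_rois):
        raise ValueError(
            f"frame count {n_frames} != ROI log length {len(mapped_rois)}")
    valid = np.array(flags)
    vals = np.array(values)
    if not valid.any():
        raise ThermorespError("no frame has a valid ROI; nothing to extract")
    idx = np.arange(len(vals))
    vals[~valid] = np.interp(idx[~valid], idx[valid], vals[valid])
    return RespSignal(values=vals, fs=fs, valid=valid, t0=t0)


def normalize(signal: RespSignal) -> RespSignal:
    """Z-score: zero mean, unit standard deviation."""
    x = signal.values
    if len(x) < 2:
        raise ValueError("need at least 2 samples to normalise")
    sd = float(np.std(x))
    if sd == 0:
        raise FlatSignalError("signal has zero variance")
    return signal.with_values((x - np.mean(x)) / sd)


def hampel_filter(signal: RespSignal, half_window: int,
                  n_sigma: float = 3.0, mad_floor: float = 1e-9) -> RespSignal:
    """Sliding-median spike rejector.

    A sample is replaced by its local median when it deviates by more
    than ``n_sigma * 1.4826 * MAD``; the MAD is floored at ``mad_floor``
    so that spikes in otherwise flat neighbourhoods are still rejected.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    x = signal.values
    n = len(x)
    if n == 0:
        return signal
    k = int(half_window)
    padded = np.pad(x, k, mode="reflect") if n > 1 else np.pad(x, k, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, 2 * k + 1)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    mad = np.maximum(mad, mad_floor)
    out = np.where(np.abs(x - med) > n_sigma * 1.4826 * mad, med, x)
    return signal.with_values(out)


def moving_average(signal: RespSignal, window: int) -> RespSignal:
    """Centred moving mean; partial windows shrink at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return signal
    x = signal.values
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return signal.with_values(sums / counts)


def bandpass(signal: RespSignal, band: BandConfig) -> RespSignal:
    """Zero-phase Butterworth bandpass (forward-backward filtering).

    The -3 dB points of the one-pass filter sit at the band edges; the
    forward-backward application squares the magnitude response and
    cancels phase distortion, so breathing peaks are not shifted.
    """
    nyq = signal.fs / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band edge {band.high_hz} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(band.order, [band.low_hz, band.high_hz],
                     btype="bandpass", fs=signal.fs, output="sos")
    out = sps.sosfiltfilt(sos, signal.values)
    return signal.with_values(out)


def estimate_rr_czt(signal: RespSignal | FloatArray, band: BandConfig,
                    freq_resolution: float = 0.005,
                    fs: float | None = None) -> tuple[float, float, float]:
    """Chirp-Z spectral peak in the breathing band.

    Evaluates the z-transform along the unit-circle arc covering
    ``[low_hz, high_hz]`` at ``freq_resolution`` spacing and returns
    ``(peak_freq_hz, rr_bpm, spectral_peak_ratio)`` where the ratio is
    the peak magnitude over the median in-band magnitude (a simple
    peakedness quality index).  Ties break toward the lower frequency.
    """
    if isinstance(signal, RespSignal):
        x, fs = signal.values, signal.fs
    else:
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
        x = np.asarray(signal, dtype=float)
    n = len(x)
    if n / fs < 2.0 / band.low_hz:
        raise SignalTooShortError(
            f"window of {n / fs:.1f} s holds fewer than two periods at "
            f"{band.low_hz} Hz")
    x = x - np.mean(x)
    m = int(np.floor((band.high_hz - band.low_hz) / freq_resolution)) + 1
    w = np.exp(-2j * np.pi * freq_resolution / fs)
    a = np.exp(2j * np.pi * band.low_hz / fs)
    spectrum = np.abs(sps.czt(x, m=m, w=w, a=a))
    peak_idx = int(np.argmax(spectrum))
    peak_freq = band.low_hz + peak_idx * freq_resolution
    med = float(np.median(spectrum))
    ratio = float(spectrum[peak_idx] / med) if med > 0 else np.inf
    return peak_freq, 60.0 * peak_freq, ratio


def filter_chain(signal: RespSignal, band: BandConfig,
                 hampel_half_window: int | None = None,
                 hampel_n_sigma: float = 3.0,
                 smooth_window: int | None = None) -> RespSignal:
    """The conditioning chain: normalise -> Hampel -> moving average -> bandpass."""
    fs = signal.fs
    if hampel_half_window is None:
        hampel_half_window = max(1, int(round(fs)))          # 1 s
    if smooth_window is None:
        smooth_window = max(1, int(round(fs / 3.0)) | 1)     # ~1/3 s, odd
    out = normalize(signal)
    out = hampel_filter(out, hampel_half_window, hampel_n_sigma)
    out = moving_average(out, smooth_window)
    out = bandpass(out, band)
    return out


def _max_gap_seconds(valid: NDArray[np.bool_], fs: float) -> float:
    """Longest run of invalid samples, in seconds."""
    if valid.all():
        return 0.0
    padded = np.concatenate([[True], valid, [True]])
    changes = np.flatnonzero(np.diff(padded.astype(int)))
    runs = changes[1::2] - changes[0::2]
    return float(runs.max()) / fs


def sliding_rr(signal: RespSignal, band: BandConfig,
               window_s: float = 30.0, step_s: float = 20.0,
               freq_resolution: float = 0.005,
               pause_rms_frac: float = 0.25,
               max_gap_s: float = 2.0) -> list[RRWindow]:
    """Windowed RR estimates over the whole record.

    The full conditioning chain runs once on the record; the chirp-Z
    peak is then taken per 30 s window sliding by 20 s (defaults).  A
    window whose in-band RMS falls below ``pause_rms_frac`` of the
    record RMS is scored as a breathing pause (0 bpm, low quality); a
    window overlapping an ROI-detection gap longer than ``max_gap_s``
    is flagged low quality.
    """
    fs = signal.fs
    n = len(signal)
    n_win = int(round(window_s * fs))
    n_step = int(round(step_s * fs))
    if n < n_win:
        raise SignalTooShortError(
            f"record of {n / fs:.1f} s shorter than one {window_s:.0f} s window")
    filtered = filter_chain(signal, band)
    record_rms = float(np.sqrt(np.mean(filtered.values**2)))

    out: list[RRWindow] = []
    start = 0
    while start + n_win <= n:
        seg = filtered.values[start:start + n_win]
        seg_valid = signal.valid[start:start + n_win]
        t_start = signal.t0 + start / fs
        t_end = t_start + n_win / fs
        low_quality = _max_gap_seconds(seg_valid, fs) > max_gap_s
        seg_rms = float(np.sqrt(np.mean(seg**2)))
        if record_rms > 0 and seg_rms < pause_rms_frac * record_rms:
            out.append(RRWindow(t_start, t_end, rr_bpm=0.0, peak_freq_hz=0.0,
                                spectral_peak_ratio=0.0, low_quality=True))
        else:
            f_peak, rr, ratio = estimate_rr_czt(seg, band, freq_resolution, fs=fs)
            out.append(RRWindow(t_start, t_end, rr_bpm=rr, peak_freq_hz=f_peak,
                                spectral_peak_ratio=ratio,
                                low_quality=low_quality))
        start += n_step
    return out
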