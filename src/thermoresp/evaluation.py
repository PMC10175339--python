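"""Agreement metrics between estimated and reference respiratory rates.

For measured rates ``BR_m(k)`` and reference rates ``BR_r(k)`` over N
window-aligned measurements, the absolute error is ``AE(k) = |BR_m(k) -
BR_r(k)|``, the average absolute error (AAE) is its mean and the
standard deviation error (SDE) is the sample standard deviation of AE
(N-1 denominator).  Agreement is additionally summarised by a
Bland-Altman analysis (mean difference and 1.96-SD limits of agreement)
and the Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from numpy.typing import NDArray
from scipy import stats

from .errors import FlatSignalError, ThermorespError
from .resp_signal import BandConfig, RespSignal, RRWindow, sliding_rr

__all__ = [
    "MetricsReport",
    "aae_sde",
    "bland_altman",
    "pearson_r",
    "reference_rr_from_belt",
    "compute_metrics",
    "align_windows",
]


@dataclass(frozen=True)
class MetricsReport:
    """Agreement summary between measured and reference RR series."""

    aae: float
    sde: float
    n_measurements: int
    pearson_r: float
    bland_mean_diff: float
    bland_loa_low: float
    bland_loa_high: float
    roi_success_rate: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _as_arrays(measured: Sequence[float], reference: Sequence[float],
               ) -> tuple[NDArray, NDArray]:
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError(
            f"series length mismatch: {m.shape} vs {r.shape}")
    return m, r


def aae_sde(measured: Sequence[float], reference: Sequence[float],
            ) -> tuple[float, float]:
    """Average absolute error and its sample standard deviation."""
    m, r = _as_arrays(measured, reference)
    if len(m) < 2:
        raise ValueError("need N >= 2 measurements for the SDE")
    ae = np.abs(m - r)
    aae = float(np.mean(ae))
    sde = float(np.sqrt(np.sum((ae - aae) ** 2) / (len(ae) - 1)))
    return aae, sde


def bland_altman(measured: Sequence[float], reference: Sequence[float],
                 ) -> tuple[float, float, float, NDArray, NDArray]:
    """Mean difference, limits of agreement, per-point diffs and means.

    Differences are measured - reference; the limits of agreement are
    ``mean_diff +/- 1.96 * sd(diffs)`` with the sample (N-1) SD.
    """
    m, r = _as_arrays(measured, reference)
    if len(m) < 2:
        raise ValueError("need N >= 2 measurements")
    diffs = m - r
    means = (m + r) / 2.0
    mean_diff = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd, diffs, means


def pearson_r(measured: Sequence[float], reference: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    m, r = _as_arrays(measured, reference)
    if len(m) < 3:
        raise ValueError("need N >= 3 measurements for a correlation")
    if np.std(m) == 0 or np.std(r) == 0:
        raise FlatSignalError("zero variance on one side of the correlation")
    return float(stats.pearsonr(m, r).statistic)


def reference_rr_from_belt(belt_signal: RespSignal | NDArray,
                           band: BandConfig,
                           window_s: float = 30.0, step_s: float = 20.0,
                           fs: float = 10.0) -> list[RRWindow]:
    """Window-aligned reference RR from a respiration-belt force signal.

    The belt samples chest/abdominal force at its native rate (10 Hz for
    the Go Direct belt); the identical conditioning chain and chirp-Z
    windowing used on the thermal signal is applied so measured and
    reference windows are directly comparable.
    """
    if not isinstance(belt_signal, RespSignal):
        belt_signal = RespSignal(values=np.asarray(belt_signal, dtype=float),
                                 fs=fs)
    return sliding_rr(belt_signal, band, window_s=window_s, step_s=step_s)


def align_windows(measured: Sequence[RRWindow], reference: Sequence[RRWindow],
                  tol_s: float = 0.5) -> tuple[NDArray, NDArray]:
    """Pair RR windows by start time; both series must share the grid."""
    ref_by_start = {round(w.window_start / tol_s): w for w in reference}
    m_vals, r_vals = [], []
    for w in measured:
        key = round(w.window_start / tol_s)
        if key not in ref_by_start:
            raise ThermorespError(
                f"no reference window starting near t={w.window_start:.1f} s; "
                "measured and reference must use identical window/step settings")
        m_vals.append(w.rr_bpm)
        r_vals.append(ref_by_start[key].rr_bpm)
    return np.asarray(m_vals), np.asarray(r_vals)


def compute_metrics(measured: Sequence[RRWindow],
                    reference: Sequence[RRWindow],
                    roi_success_rate: float | None = None) -> MetricsReport:
    """Full agreement report between two window-aligned RR series."""
    m, r = align_windows(measured, reference)
    aae, sde = aae_sde(m, r)
    mean_diff, loa_low, loa_high, _, _ = bland_altman(m, r)
    try:
        corr = pearson_r(m, r)
    except (FlatSignalError, ValueError):
        corr = float("nan")
    return MetricsReport(aae=aae, sde=sde, n_measurements=len(m),
                         pearson_r=corr, bland_mean_diff=mean_diff,
                         bland_loa_low=loa_low, bland_loa_high=loa_high,
                         roi_success_rate=roi_success_rate)
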