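"""Nostril-ROI geometry and the tracking-by-detection selection operator.

The nostril region of interest is derived from five facial landmarks:
with nose tip ``(nx, ny)`` and mouth corners ``(mlx, mly)``/``(mrx, mry)``,

    eta   = round(sqrt((mlx - nx)^2 + (mly - ny)^2) / 4)
    omega = round(|mlx - mrx| / 2)
    ROI   = [nx - omega, ny - eta, 2*omega, 3*eta]

Frame-to-frame the ROI is maintained by alternating a landmark detector
and a correlation tracker under a selection operator: while both the
tracking status ``t_s`` and detection status ``d_s`` are True the next
frame is tracked; as soon as either goes False tracking is disabled and
detection takes over, reinitialising the tracker on the next success.
Rounding is half-to-even throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Protocol

import numpy as np
from numpy.typing import NDArray
from skimage.feature import match_template

from . import fiducials
from .errors import DegenerateLandmarksError, ThermorespError

__all__ = [
    "Landmarks5",
    "ROIBox",
    "TrackingConfig",
    "TDRecord",
    "TDState",
    "LandmarkDetector",
    "FiducialDetector",
    "NccTracker",
    "roi_from_landmarks",
    "detect_landmarks",
    "td_step",
    "run_td",
    "roi_success_rate",
    "td_log_frame",
]


@dataclass(frozen=True)
class Landmarks5:
    """Five-point facial landmarks in pixel coordinates (x=column, y=row)."""

    left_eye: tuple[float, float]
    right_eye: tuple[float, float]
    nose_tip: tuple[float, float]
    mouth_left: tuple[float, float]
    mouth_right: tuple[float, float]
    confidence: float = 1.0

    def as_array(self) -> NDArray[np.float64]:
        return np.array([self.left_eye, self.right_eye, self.nose_tip,
                         self.mouth_left, self.mouth_right], dtype=float)


@dataclass(frozen=True)
class ROIBox:
    """Rectangle ``[bx, by, w, h]``, half-open in both axes, 0-based."""

    bx: int
    by: int
    w: int
    h: int
    frame_id: int = -1
    coord_frame: str = "visible"
    eta: int | None = None
    omega: int | None = None

    @property
    def valid(self) -> bool:
        return self.w >= 1 and self.h >= 1

    @property
    def center(self) -> tuple[float, float]:
        return (self.bx + self.w / 2.0, self.by + self.h / 2.0)

    def corners(self) -> NDArray[np.float64]:
        """The 4 corner points of the half-open box, (x, y) rows."""
        return np.array([
            [self.bx, self.by],
            [self.bx + self.w, self.by],
            [self.bx + self.w, self.by + self.h],
            [self.bx, self.by + self.h],
        ], dtype=float)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.by, self.by + self.h), slice(self.bx, self.bx + self.w)

    def clipped(self, shape: tuple[int, int]) -> "ROIBox":
        h, w = shape[0], shape[1]
        x0 = min(max(self.bx, 0), w)
        y0 = min(max(self.by, 0), h)
        x1 = min(max(self.bx + self.w, 0), w)
        y1 = min(max(self.by + self.h, 0), h)
        return replace(self, bx=x0, by=y0, w=x1 - x0, h=y1 - y0)


def roi_from_landmarks(lm: Landmarks5, frame_shape: tuple[int, int] | None = None,
                       frame_id: int = -1) -> ROIBox:
    """Nostril ROI from nose tip and mouth corners (see module docstring)."""
    nx, ny = lm.nose_tip
    mlx, mly = lm.mouth_left
    mrx, _ = lm.mouth_right
    eta = int(np.round(np.hypot(mlx - nx, mly - ny) / 4.0))
    omega = int(np.round(abs(mlx - mrx) / 2.0))
    if eta == 0 or omega == 0:
        raise DegenerateLandmarksError(
            f"degenerate landmark geometry: eta={eta}, omega={omega}")
    box = ROIBox(bx=int(np.round(nx)) - omega, by=int(np.round(ny)) - eta,
                 w=2 * omega, h=3 * eta, frame_id=frame_id,
                 coord_frame="visible", eta=eta, omega=omega)
    if frame_shape is not None:
        box = box.clipped(frame_shape)
    return box


class LandmarkDetector(Protocol):
    """Contract for landmark detectors.

    ``detect`` returns the landmarks (with a confidence in [0, 1]) or
    ``None`` when nothing was found.  ``region`` = (x0, y0, x1, y1) is an
    optional search window hint; detectors are free to ignore it.
    """

    def detect(self, frame: NDArray, region: tuple[int, int, int, int] | None = None,
               ) -> Landmarks5 | None: ...


class FiducialDetector:
    """Bundled detector locating the synthetic colour-coded fiducials.

    An adapter for an external pretrained face/landmark network can be
    plugged in anywhere a :class:`LandmarkDetector` is accepted; this
    implementation only understands the markers planted by the
    synthetic-scene generator.
    """

    def __init__(self, radius: int = fiducials.DEFAULT_RADIUS, color_tol: int = 60):
        self.radius = radius
        self.color_tol = color_tol

    def detect(self, frame: NDArray, region: tuple[int, int, int, int] | None = None,
               ) -> Landmarks5 | None:
        points: dict[str, tuple[float, float]] = {}
        confs = []
        for name in fiducials.LANDMARK_NAMES:
            pt, conf = fiducials.find_fiducial(
                frame, fiducials.FIDUCIAL_COLORS[name],
                radius=self.radius, tol=self.color_tol, region=region)
            if pt is None:
                return None
            points[name] = pt
            confs.append(conf)
        return Landmarks5(confidence=float(min(confs)), **points)  # type: ignore[arg-type]


def detect_landmarks(frame: NDArray, detector: LandmarkDetector,
                     min_confidence: float = 0.6,
                     region: tuple[int, int, int, int] | None = None,
                     ) -> tuple[Landmarks5 | None, bool]:
    """Run a detector; ``d_s`` is True iff confidence meets the threshold.

    Detector exceptions are swallowed into a failed detection so that a
    flaky detector cannot crash the per-frame loop.
    """
    try:
        lm = detector.detect(frame, region=region)
    except Exception:
        return None, False
    if lm is None or lm.confidence < min_confidence:
        return None, False
    return lm, True


def _to_gray(frame: NDArray) -> NDArray[np.float64]:
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    return arr


class NccTracker:
    """Normalised-cross-correlation template tracker.

    The template is the grayscale ROI patch; each update searches a
    window around the previous position, takes the correlation peak as
    the new position and its NCC value as the quality score, and blends
    the template toward the new appearance with a small learning rate so
    slow appearance drift is absorbed without locking onto occluders.
    """

    def __init__(self, frame: NDArray, box: ROIBox,
                 search_margin: int = 20, learning_rate: float = 0.075,
                 update_quality: float = 0.5):
        gray = _to_gray(frame)
        box = box.clipped(gray.shape)
        if not box.valid:
            raise ThermorespError("cannot initialise tracker on an empty box")
        self.box = box
        self.search_margin = int(search_margin)
        self.learning_rate = float(learning_rate)
        self.update_quality = float(update_quality)
        self.template = gray[box.slices()].copy()

    def update(self, frame: NDArray) -> tuple[ROIBox, float]:
        gray = _to_gray(frame)
        h, w = gray.shape
        th, tw = self.template.shape
        m = self.search_margin
        x0 = max(0, self.box.bx - m)
        y0 = max(0, self.box.by - m)
        x1 = min(w, self.box.bx + tw + m)
        y1 = min(h, self.box.by + th + m)
        search = gray[y0:y1, x0:x1]
        if search.shape[0] < th or search.shape[1] < tw:
            return self.box, 0.0
        resp = match_template(search, self.template)
        peak = np.unravel_index(np.argmax(resp), resp.shape)
        quality = float(resp[peak])
        if not np.isfinite(quality):
            quality = 0.0
        new_box = replace(self.box, bx=x0 + int(peak[1]), by=y0 + int(peak[0]))
        if quality >= self.update_quality:
            self.box = new_box
            patch = gray[new_box.slices()]
            if patch.shape == self.template.shape:
                lr = self.learning_rate
                self.template = (1.0 - lr) * self.template + lr * patch
        return new_box, quality


@dataclass(frozen=True)
class TrackingConfig:
    """Thresholds of the tracking-by-detection loop."""

    detection_confidence: float = 0.6
    tracking_quality: float = 0.5
    template_learning_rate: float = 0.075
    search_margin: int = 20
    min_box_px: int = 2          # boxes thinner than this count as failures
    detection_region_margin: int = 120   # search-window halo around last ROI


@dataclass(frozen=True)
class TDRecord:
    """Per-frame outcome of the selection operator."""

    frame_id: int
    mode: str                 # mode the frame was processed in
    roi: ROIBox | None
    t_s: bool
    d_s: bool
    quality: float


@dataclass
class TDState:
    """Mutable state of the tracking-by-detection loop."""

    mode: str = "detecting"
    current_roi: ROIBox | None = None
    tracker: NccTracker | None = None
    last_landmarks: Landmarks5 | None = None
    log: list[TDRecord] = field(default_factory=list)

    @property
    def t_s(self) -> bool:
        return bool(self.log) and self.log[-1].t_s

    @property
    def d_s(self) -> bool:
        return bool(self.log) and self.log[-1].d_s


def _detection_region(state: TDState, frame_shape: tuple[int, int],
                      config: TrackingConfig) -> tuple[int, int, int, int] | None:
    """Limit detection to a halo around the last known ROI when available."""
    roi = state.current_roi
    if roi is None or not roi.valid:
        return None
    m = config.detection_region_margin
    return (roi.bx - m, roi.by - m, roi.bx + roi.w + m, roi.by + roi.h + m)


TrackerFactory = Callable[[NDArray, ROIBox], NccTracker]


def td_step(state: TDState, frame: NDArray, detector: LandmarkDetector,
            config: TrackingConfig | None = None,
            tracker_factory: TrackerFactory | None = None) -> TDState:
    """Advance the selection operator by one frame (mutates ``state``).

    Detection runs on every frame (it supplies ``d_s``); the tracker
    runs only while the loop is in tracking mode.  Transition rule:
    next mode is tracking iff both ``t_s`` and ``d_s`` are True this
    frame, where a tracker freshly (re)initialised from a successful
    detection counts as a healthy tracker.
    """
    config = config or TrackingConfig()
    if tracker_factory is None:
        def tracker_factory(f, b):  # type: ignore[misc]
            return NccTracker(f, b, search_margin=config.search_margin,
                              learning_rate=config.template_learning_rate,
                              update_quality=config.tracking_quality)
    frame_id = len(state.log)
    frame_shape = np.shape(frame)[:2]
    mode = state.mode

    # while tracking, detection only needs to confirm the target near the
    # current ROI; in detecting mode the whole frame is searched
    region = (_detection_region(state, frame_shape, config)
              if mode == "tracking" else None)
    lm, d_s = detect_landmarks(frame, detector, config.detection_confidence,
                               region=region)
    det_roi: ROIBox | None = None
    if d_s:
        try:
            det_roi = roi_from_landmarks(lm, frame_shape, frame_id=frame_id)
        except DegenerateLandmarksError:
            d_s, det_roi = False, None
        else:
            if det_roi.w < config.min_box_px or det_roi.h < config.min_box_px:
                d_s, det_roi = False, None

    quality = 0.0
    t_s = False
    tracked_roi: ROIBox | None = None
    if mode == "tracking" and state.tracker is not None:
        box, quality = state.tracker.update(frame)
        t_s = quality >= config.tracking_quality
        if t_s:
            tracked_roi = replace(box, frame_id=frame_id)

    if mode == "tracking" and t_s:
        roi = tracked_roi
    else:
        roi = det_roi

    # in detecting mode a successful detection (re)initialises the
    # tracker, and that fresh tracker counts as t_s = True so the next
    # frame switches to tracking; a failed *tracking* frame keeps its
    # t_s = False regardless, so the operator falls back to detection
    # for at least one frame
    if mode == "detecting" and det_roi is not None:
        try:
            state.tracker = tracker_factory(frame, det_roi)
            t_s = True
        except ThermorespError:
            state.tracker = None
            t_s = False

    state.log.append(TDRecord(frame_id=frame_id, mode=mode, roi=roi,
                              t_s=t_s, d_s=d_s, quality=quality))
    state.current_roi = roi if (roi is not None and roi.valid) else state.current_roi
    if lm is not None:
        state.last_landmarks = lm
    state.mode = "tracking" if (t_s and d_s) else "detecting"
    return state


def run_td(frames: Iterable[NDArray], detector: LandmarkDetector,
           config: TrackingConfig | None = None,
           tracker_factory: TrackerFactory | None = None) -> TDState:
    """Run the tracking-by-detection loop over a frame sequence."""
    state = TDState()
    for frame in frames:
        td_step(state, frame, detector, config, tracker_factory)
    return state


def roi_success_rate(log: list[TDRecord]) -> float:
    """Percentage of frames with a valid ROI: 100 * detected / total."""
    if not log:
        raise ThermorespError("ROI log is empty")
    n_ok = sum(1 for rec in log if rec.roi is not None and rec.roi.valid)
    return 100.0 * n_ok / len(log)


def td_log_frame(log: list[TDRecord]):
    """ROI log as a pandas DataFrame (frame_id, mode, box, statuses)."""
    import pandas as pd

    rows = []
    for rec in log:
        roi = rec.roi
        rows.append({
            "frame_id": rec.frame_id, "mode": rec.mode,
            "bx": roi.bx if roi else -1, "by": roi.by if roi else -1,
            "w": roi.w if roi else 0, "h": roi.h if roi else 0,
            "t_s": rec.t_s, "d_s": rec.d_s, "quality": rec.quality,
        })
    return pd.DataFrame(rows)
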