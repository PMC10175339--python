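"""Ground-truthed synthetic RGB-T recordings.

No public dataset accompanies this problem, so every pipeline stage is
exercised on synthetic paired recordings built here: a thermal scene
whose nostril patch oscillates in temperature at a known breathing
frequency (nasal airflow is the physical basis — exhaled air is warmer
than inhaled air), a visible stream carrying colour-coded fiducial
markers at the five facial landmark positions, a known affine transform
between the two camera frames, checkerboard calibration-rig frames
rendered in both modalities, and optional head-motion and occlusion
events.  All randomness flows from a single integer seed; frames are
synthesised lazily so long recordings never need to fit in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import NDArray
from skimage.transform import AffineTransform, warp

from . import fiducials
from .registration import AffineMap
from .roi_tracking import Landmarks5

__all__ = [
    "BreathingWaveform",
    "mode_c_waveform",
    "MotionEvent",
    "SceneSpec",
    "GroundTruth",
    "SyntheticRGBTSequence",
    "generate_scene",
    "generate_rig_pair",
    "generate_structured_pair",
]

FloatArray = NDArray[np.floating]


# ---------------------------------------------------------------------------
# breathing waveform


@dataclass(frozen=True)
class BreathingWaveform:
    """Piecewise-constant-rate sinusoid with continuous phase.

    ``segments`` is a list of ``(duration_s, rate_bpm_or_None)``; a
    ``None`` rate is a breathing pause rendered as a zero-amplitude
    stretch.  Phase accumulates continuously across segment joins and
    the amplitude envelope cross-fades with a raised cosine so the
    waveform has no step discontinuities.
    """

    segments: tuple[tuple[float, float | None], ...]
    ramp_s: float = 1.5

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("waveform needs at least one segment")
        for dur, rate in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if rate is not None and not (6.0 < rate < 120.0):
                raise ValueError(f"rate {rate} bpm outside the plausible "
                                 "(6, 120) bpm range")

    @classmethod
    def constant(cls, rate_bpm: float, duration_s: float) -> "BreathingWaveform":
        return cls(segments=((duration_s, rate_bpm),))

    @property
    def duration_s(self) -> float:
        return sum(d for d, _ in self.segments)

    @property
    def max_rate_bpm(self) -> float:
        rates = [r for _, r in self.segments if r is not None]
        return max(rates) if rates else 0.0

    def _boundaries(self) -> FloatArray:
        return np.concatenate([[0.0], np.cumsum([d for d, _ in self.segments])])

    def rate_bpm(self, t: FloatArray) -> FloatArray:
        """Instantaneous rate (bpm); 0 during pauses and past the end."""
        t = np.asarray(t, dtype=float)
        bounds = self._boundaries()
        out = np.zeros_like(t)
        for i, (dur, rate) in enumerate(self.segments):
            mask = (t >= bounds[i]) & (t < bounds[i + 1])
            out[mask] = 0.0 if rate is None else rate
        return out

    def _phase(self, t: FloatArray) -> FloatArray:
        """2*pi * integral of the instantaneous frequency (Hz)."""
        t = np.asarray(t, dtype=float)
        bounds = self._boundaries()
        phase0 = 0.0
        out = np.zeros_like(t)
        for i, (dur, rate) in enumerate(self.segments):
            f = 0.0 if rate is None else rate / 60.0
            mask = (t >= bounds[i]) & (t <= bounds[i + 1] + 1e-12)
            out[mask] = phase0 + 2 * np.pi * f * (t[mask] - bounds[i])
            phase0 += 2 * np.pi * f * dur
        return out

    def _envelope(self, t: FloatArray) -> FloatArray:
        t = np.asarray(t, dtype=float)
        bounds = self._boundaries()
        amps = [0.0 if r is None else 1.0 for _, r in self.segments]
        # base amplitude of the covering segment
        seg_idx = np.clip(np.searchsorted(bounds, t, side="right") - 1,
                          0, len(amps) - 1)
        env = np.asarray([amps[i] for i in seg_idx.ravel()],
                         dtype=float).reshape(t.shape)
        # raised-cosine cross-fades at joins where amplitude changes
        for j in range(1, len(self.segments)):
            a0, a1 = amps[j - 1], amps[j]
            if a0 == a1:
                continue
            ramp = min(self.ramp_s,
                       self.segments[j - 1][0] / 2, self.segments[j][0] / 2)
            tj = bounds[j]
            in_ramp = np.abs(t - tj) < ramp / 2
            u = (t[in_ramp] - tj + ramp / 2) / ramp  # 0 -> 1 across the ramp
            env[in_ramp] = a0 + (a1 - a0) * (0.5 - 0.5 * np.cos(np.pi * u))
        return env

    def sample(self, t: FloatArray) -> FloatArray:
        """Dimensionless waveform value(s) in [-1, 1] at time(s) t."""
        t = np.asarray(t, dtype=float)
        return self._envelope(t) * np.sin(self._phase(t))


def mode_c_waveform(segments: Sequence[tuple[float, float | None]],
                    ) -> BreathingWaveform:
    """Varying-order breathing: e.g. normal, fast, then a pause."""
    return BreathingWaveform(segments=tuple(segments))


# ---------------------------------------------------------------------------
# scene specification


@dataclass(frozen=True)
class MotionEvent:
    """Uniform head translation (visible px/s) over [t1, t2]."""

    t1: float
    t2: float
    vx: float
    vy: float


@dataclass(frozen=True)
class SceneSpec:
    """Everything that defines one synthetic RGB-T recording."""

    duration_s: float
    seed: int
    fps: float = 30.0
    rgb_shape: tuple[int, int] = (720, 960)       # (rows, cols)
    thermal_shape: tuple[int, int] = (240, 320)
    true_map: AffineMap | None = None             # default: scale 1/3 + shift
    breathing: BreathingWaveform | None = None
    rate_bpm: float = 48.0                        # used when breathing is None
    amplitude_c: float = 0.4                      # nostril oscillation, deg C
    baseline_c: float = 34.0                      # nostril baseline, deg C
    snr_db: float | None = None                   # patch-trace SNR
    noise_sd_c: float | None = None               # overrides snr_db if set
    pixel_noise_c: float = 0.05                   # per-pixel sensor noise
    motion: tuple[MotionEvent, ...] = ()
    occlusions: tuple[tuple[float, float], ...] = ()
    rig_corners: tuple[int, int] = (5, 6)         # inner-corner (rows, cols)
    n_background_rects: int = 40

    def resolved_waveform(self) -> BreathingWaveform:
        if self.breathing is not None:
            return self.breathing
        return BreathingWaveform.constant(self.rate_bpm, self.duration_s)

    def resolved_map(self) -> AffineMap:
        if self.true_map is not None:
            return self.true_map
        return AffineMap.from_similarity(1.0 / 3.0, 2.0, -1.0, provenance="rig")

    def resolved_noise_sd(self) -> float:
        if self.noise_sd_c is not None:
            return self.noise_sd_c
        if self.snr_db is not None:
            # SNR = (A^2/2) / sigma^2 for a sinusoid of amplitude A
            return self.amplitude_c / np.sqrt(2.0 * 10.0 ** (self.snr_db / 10.0))
        return 0.0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        wave = self.resolved_waveform()
        if wave.max_rate_bpm / 60.0 >= self.fps / 2.0:
            raise ValueError("breathing rate violates the thermal Nyquist limit")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _base_landmarks(rgb_shape: tuple[int, int]) -> dict[str, tuple[float, float]]:
    h, w = rgb_shape
    return {
        "left_eye": (0.448 * w, 0.319 * h),
        "right_eye": (0.552 * w, 0.319 * h),
        "nose_tip": (0.500 * w, 0.458 * h),
        "mouth_left": (0.458 * w, 0.569 * h),
        "mouth_right": (0.542 * w, 0.569 * h),
    }


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame truth for a synthetic recording."""

    landmarks_visible: FloatArray          # (n_frames, 5, 2) in fiducial order
    landmark_present: NDArray[np.bool_]    # False during occlusions
    patch_trace_clean: FloatArray          # noise-free nostril temperature
    rate_bpm_trace: FloatArray             # instantaneous truth per frame
    true_map: AffineMap
    fps: float

    def landmarks_thermal(self) -> FloatArray:
        flat = self.landmarks_visible.reshape(-1, 2)
        return self.true_map.apply(flat).reshape(self.landmarks_visible.shape)

    def landmarks_at(self, i: int) -> Landmarks5 | None:
        if not self.landmark_present[i]:
            return None
        pts = self.landmarks_visible[i]
        names = fiducials.LANDMARK_NAMES
        return Landmarks5(**{n: tuple(p) for n, p in zip(names, pts)})

    def true_rr_windows(self, window_s: float = 30.0, step_s: float = 20.0,
                        ) -> list[tuple[float, float, float]]:
        """(start, end, mean rate bpm) per sliding window, matching the
        analysis windowing arithmetic."""
        n = len(self.rate_bpm_trace)
        n_win = int(round(window_s * self.fps))
        n_step = int(round(step_s * self.fps))
        out = []
        start = 0
        while start + n_win <= n:
            rr = float(np.mean(self.rate_bpm_trace[start:start + n_win]))
            out.append((start / self.fps, (start + n_win) / self.fps, rr))
            start += n_step
        return out


def _int_shift(img: FloatArray, dx: int, dy: int) -> FloatArray:
    """Shift a 2-D array by integer pixels, zero-filling the border."""
    out = np.zeros_like(img)
    h, w = img.shape
    sy0, sy1 = max(0, dy), min(h, h + dy)
    sx0, sx1 = max(0, dx), min(w, w + dx)
    out[sy0:sy1, sx0:sx1] = img[sy0 - dy:sy1 - dy, sx0 - dx:sx1 - dx]
    return out


class SyntheticRGBTSequence:
    """Lazily synthesised paired visible/thermal frame streams."""

    def __init__(self, spec: SceneSpec):
        spec.validate()
        self.spec = spec
        self.fps = spec.fps
        self.n_frames = int(round(spec.duration_s * spec.fps))
        self.rgb_shape = spec.rgb_shape
        self.thermal_shape = spec.thermal_shape
        self.true_map = spec.resolved_map()
        self._build_static()
        self._build_truth()

    # -- static layers ----------------------------------------------------
    def _build_static(self) -> None:
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        h, w = spec.rgb_shape
        canvas = np.full((h, w), 0.5)
        for _ in range(spec.n_background_rects):
            rw = rng.integers(30, 150)
            rh = rng.integers(30, 150)
            x0 = rng.integers(0, max(1, w - rw))
            y0 = rng.integers(0, max(1, h - rh))
            canvas[y0:y0 + rh, x0:x0 + rw] = rng.uniform(0.15, 0.85)
        self._canvas = canvas
        self._rgb_base = np.repeat((canvas * 255).astype(np.uint8)[:, :, None],
                                   3, axis=2)

        lm = _base_landmarks(spec.rgb_shape)
        self._landmarks0 = np.array([lm[n] for n in fiducials.LANDMARK_NAMES])
        nose = np.array(lm["nose_tip"])
        mouth_l = np.array(lm["mouth_left"])
        mouth_r = np.array(lm["mouth_right"])
        omega = abs(mouth_l[0] - mouth_r[0]) / 2.0
        eta = np.hypot(*(mouth_l - nose)) / 4.0

        # thermal scene in visible coordinates: cool textured background
        # (inverted contrast vs the visible canvas), a warm face ellipse,
        # and the nostril patch at its baseline temperature
        t_bg_vis = 26.0 + 6.0 * (1.0 - canvas)
        yy, xx = np.mgrid[0:h, 0:w]
        eye_c = (self._landmarks0[0] + self._landmarks0[1]) / 2.0
        face_c = (eye_c + (mouth_l + mouth_r) / 2.0) / 2.0
        ax, ay = 0.14 * w, 0.20 * h
        face_mask = (((xx - face_c[0]) / ax) ** 2
                     + ((yy - face_c[1]) / ay) ** 2) <= 1.0
        patch_mask_vis = ((np.abs(xx - nose[0]) <= 0.8 * omega)
                          & (yy >= nose[1] + 0.1 * eta)
                          & (yy <= nose[1] + 1.8 * eta))
        t_static_vis = t_bg_vis.copy()
        t_static_vis[face_mask] = 33.5
        t_static_vis[patch_mask_vis] = spec.baseline_c
        self._occluder_box_vis = self._face_bbox(margin=30)

        # visible face appearance: a shaded ellipse with mild speckle so
        # the correlation tracker has texture that moves with the subject
        x0, y0, x1, y1 = self._face_bbox(margin=10)
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(w, x1), min(h, y1)
        fyy, fxx = np.mgrid[y0:y1, x0:x1]
        r2 = (((fxx - face_c[0]) / ax) ** 2 + ((fyy - face_c[1]) / ay) ** 2)
        fmask = r2 <= 1.0
        shading = np.clip(1.0 - 0.5 * r2, 0.0, 1.0)
        speckle = rng.uniform(-0.12, 0.12, size=fmask.shape)
        face_gray = np.clip(0.45 + 0.35 * shading + speckle, 0.0, 1.0)
        self._face_anchor = (x0, y0)
        self._face_mask = fmask
        self._face_patch = (face_gray * 255).astype(np.uint8)

        inv = AffineTransform(matrix=self.true_map.inverse().as_3x3())
        th_shape = spec.thermal_shape
        self._t_bg_th = warp(t_bg_vis, inv, output_shape=th_shape,
                             mode="edge", preserve_range=True)
        t_static_th = warp(t_static_vis, inv, output_shape=th_shape,
                           mode="edge", preserve_range=True)
        self._subject_delta_th = t_static_th - self._t_bg_th
        self._patch_mask_th = warp(patch_mask_vis.astype(float), inv,
                                   output_shape=th_shape, mode="constant",
                                   preserve_range=True)

    def _face_bbox(self, margin: int = 30) -> tuple[int, int, int, int]:
        pts = self._landmarks0
        x0 = int(pts[:, 0].min()) - margin
        y0 = int(pts[:, 1].min()) - margin
        x1 = int(pts[:, 0].max()) + margin
        y1 = int(pts[:, 1].max()) + margin
        return x0, y0, x1, y1

    # -- per-frame truth --------------------------------------------------
    def _build_truth(self) -> None:
        spec = self.spec
        n = self.n_frames
        t = np.arange(n) / spec.fps
        wave = spec.resolved_waveform()
        self._wave_vals = wave.sample(t)
        rate = wave.rate_bpm(t)

        noise_sd = spec.resolved_noise_sd()
        trace_rng = np.random.default_rng((spec.seed, 1))
        self._patch_noise = (trace_rng.normal(0.0, noise_sd, size=n)
                             if noise_sd > 0 else np.zeros(n))

        offsets = np.zeros((n, 2))
        for ev in spec.motion:
            dt = 1.0 / spec.fps
            moving = (t >= ev.t1) & (t < ev.t2)
            vel = np.zeros((n, 2))
            vel[moving] = (ev.vx, ev.vy)
            offsets += np.cumsum(vel * dt, axis=0)
        self._offsets_vis = offsets

        present = np.ones(n, dtype=bool)
        for t1, t2 in spec.occlusions:
            present &= ~((t >= t1) & (t < t2))
        clean = spec.baseline_c + spec.amplitude_c * self._wave_vals

        self.ground_truth = GroundTruth(
            landmarks_visible=self._landmarks0[None, :, :] + offsets[:, None, :],
            landmark_present=present,
            patch_trace_clean=clean,
            rate_bpm_trace=rate,
            true_map=self.true_map,
            fps=spec.fps,
        )

    def _occluded(self, i: int) -> bool:
        return not self.ground_truth.landmark_present[i]

    # -- frame synthesis --------------------------------------------------
    def _blit_face(self, frame: NDArray[np.uint8], off) -> None:
        h, w = frame.shape[:2]
        ph, pw = self._face_patch.shape
        x0 = int(round(self._face_anchor[0] + off[0]))
        y0 = int(round(self._face_anchor[1] + off[1]))
        fx0, fy0 = max(0, -x0), max(0, -y0)
        x0, y0 = max(0, x0), max(0, y0)
        x1 = min(w, x0 + pw - fx0)
        y1 = min(h, y0 + ph - fy0)
        if x0 >= x1 or y0 >= y1:
            return
        sub_mask = self._face_mask[fy0:fy0 + y1 - y0, fx0:fx0 + x1 - x0]
        sub_patch = self._face_patch[fy0:fy0 + y1 - y0, fx0:fx0 + x1 - x0]
        region = frame[y0:y1, x0:x1]
        region[sub_mask] = sub_patch[sub_mask, None]

    def rgb_frame(self, i: int) -> NDArray[np.uint8]:
        frame = self._rgb_base.copy()
        off = self._offsets_vis[i]
        if self._occluded(i):
            x0, y0, x1, y1 = self._occluder_box_vis
            x0 = max(0, int(x0 + off[0]))
            y0 = max(0, int(y0 + off[1]))
            x1 = min(frame.shape[1], int(x1 + off[0]))
            y1 = min(frame.shape[0], int(y1 + off[1]))
            frame[y0:y1, x0:x1] = 110
            return frame
        self._blit_face(frame, off)
        for name, base in zip(fiducials.LANDMARK_NAMES, self._landmarks0):
            fiducials.draw_fiducial(frame, (base[0] + off[0], base[1] + off[1]),
                                    fiducials.FIDUCIAL_COLORS[name])
        return frame

    def thermal_frame(self, i: int) -> NDArray[np.float32]:
        spec = self.spec
        off_th = self.true_map.matrix[:, :2] @ self._offsets_vis[i]
        dx, dy = int(round(off_th[0])), int(round(off_th[1]))
        osc = spec.amplitude_c * self._wave_vals[i] + self._patch_noise[i]
        subject = self._subject_delta_th + self._patch_mask_th * osc
        frame = self._t_bg_th + _int_shift(subject, dx, dy)
        if self._occluded(i):
            frame = self._t_bg_th.copy()
            x0, y0, x1, y1 = self._occluder_box_vis
            off_vis = self._offsets_vis[i]
            box = self.true_map.apply(np.array(
                [[x0, y0], [x1, y1]], dtype=float) + off_vis)
            bx0, by0 = np.floor(box.min(axis=0)).astype(int)
            bx1, by1 = np.ceil(box.max(axis=0)).astype(int)
            bx0, by0 = max(0, bx0), max(0, by0)
            bx1 = min(frame.shape[1], bx1)
            by1 = min(frame.shape[0], by1)
            frame[by0:by1, bx0:bx1] = 29.0
        if spec.pixel_noise_c > 0:
            frame_rng = np.random.default_rng((spec.seed, 2, i))
            frame = frame + frame_rng.normal(0.0, spec.pixel_noise_c,
                                             size=frame.shape)
        return frame.astype(np.float32)

    def iter_rgb(self):
        for i in range(self.n_frames):
            yield self.rgb_frame(i)

    def iter_thermal(self):
        for i in range(self.n_frames):
            yield self.thermal_frame(i)


def generate_scene(spec: SceneSpec) -> tuple[SyntheticRGBTSequence, GroundTruth]:
    """Synthesise a paired recording and its ground truth."""
    seq = SyntheticRGBTSequence(spec)
    return seq, seq.ground_truth


# ---------------------------------------------------------------------------
# calibration rig


def generate_rig_pair(rig_corners: tuple[int, int] = (5, 6),
                      true_map: AffineMap | None = None,
                      rgb_shape: tuple[int, int] = (720, 960),
                      thermal_shape: tuple[int, int] = (240, 320),
                      cell_px: float | None = None,
                      ) -> tuple[NDArray[np.uint8], NDArray[np.float32], AffineMap]:
    """Checkerboard calibration frames in both modalities.

    The board pattern is evaluated analytically at every pixel of each
    modality (thermal pixels are mapped back through ``true_map``), so
    the two renderings share exact sub-pixel corner geometry.  The
    thermal board has inverted contrast, emulating a rig cut from a
    poorly conducting material.
    """
    rows, cols = rig_corners
    if min(rows, cols) < 3 or max(rows, cols) < 4:
        raise ValueError("rig grid must have at least 4x3 inner corners")
    if true_map is None:
        true_map = AffineMap.from_similarity(1.0 / 3.0, 2.0, -1.0,
                                             provenance="rig")
    h, w = rgb_shape
    if cell_px is None:
        cell_px = np.floor(0.6 * min(h, w) / (max(rows, cols) + 1))
    bw = (cols + 1) * cell_px
    bh = (rows + 1) * cell_px
    ox, oy = (w - bw) / 2.0, (h - bh) / 2.0

    def pattern(u: FloatArray, v: FloatArray) -> FloatArray:
        p = (np.sin(np.pi * (u - ox) / cell_px)
             * np.sin(np.pi * (v - oy) / cell_px))
        s = np.tanh(p / 0.1)
        inside = (u >= ox) & (u <= ox + bw) & (v >= oy) & (v <= oy + bh)
        return np.where(inside, s, 0.0)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    vis = 0.5 + 0.45 * pattern(xx, yy)
    rgb = np.repeat((vis * 255).astype(np.uint8)[:, :, None], 3, axis=2)

    th_h, th_w = thermal_shape
    tyy, txx = np.mgrid[0:th_h, 0:th_w].astype(float)
    back = true_map.inverse().apply(np.column_stack([txx.ravel(), tyy.ravel()]))
    thermal = (30.0 - 3.0 * pattern(back[:, 0], back[:, 1])
               ).reshape(th_h, th_w).astype(np.float32)
    return rgb, thermal, true_map


def rig_inner_corners_visible(rig_corners: tuple[int, int] = (5, 6),
                              rgb_shape: tuple[int, int] = (720, 960),
                              cell_px: float | None = None) -> FloatArray:
    """Ground-truth inner-corner lattice of :func:`generate_rig_pair`,
    (x, y) rows in row-major order, in visible coordinates."""
    rows, cols = rig_corners
    h, w = rgb_shape
    if cell_px is None:
        cell_px = np.floor(0.6 * min(h, w) / (max(rows, cols) + 1))
    bw = (cols + 1) * cell_px
    bh = (rows + 1) * cell_px
    ox, oy = (w - bw) / 2.0, (h - bh) / 2.0
    pts = [(ox + i * cell_px, oy + j * cell_px)
           for j in range(1, rows + 1) for i in range(1, cols + 1)]
    return np.array(pts, dtype=float)


# ---------------------------------------------------------------------------
# structured multimodal pairs for registration experiments


def generate_structured_pair(seed: int, scale: float = 3.0,
                             rotation_deg: float = 0.0,
                             translation: tuple[float, float] = (0.0, 0.0),
                             rgb_shape: tuple[int, int] = (720, 960),
                             thermal_shape: tuple[int, int] = (240, 320),
                             n_rects: int = 60,
                             ) -> tuple[NDArray[np.uint8], NDArray[np.float32],
                                        AffineMap]:
    """A random rectangle scene rendered in both modalities.

    ``scale`` is the visible/thermal resolution ratio; the returned map
    (visible -> thermal, scale ``1/scale`` with the given rotation and
    translation in thermal pixels) is the ground truth to recover.  The
    thermal rendering inverts the intensities so the pair is genuinely
    multimodal: only structure, not intensity, is shared.
    """
    rng = np.random.default_rng(seed)
    h, w = rgb_shape
    canvas = np.full((h, w), 0.5)
    for _ in range(n_rects):
        rw = rng.integers(40, 180)
        rh = rng.integers(40, 180)
        x0 = rng.integers(0, max(1, w - rw))
        y0 = rng.integers(0, max(1, h - rh))
        canvas[y0:y0 + rh, x0:x0 + rw] = rng.uniform(0.1, 0.9)
    rgb = np.repeat((canvas * 255).astype(np.uint8)[:, :, None], 3, axis=2)

    true_map = AffineMap.from_similarity(
        1.0 / scale, translation[0], translation[1],
        rotation=np.deg2rad(rotation_deg), provenance="rig")
    inv = AffineTransform(matrix=true_map.inverse().as_3x3())
    warped = warp(canvas, inv, output_shape=thermal_shape, mode="edge",
                  preserve_range=True)
    thermal = (25.0 + 10.0 * (1.0 - warped)).astype(np.float32)
    return rgb, thermal, true_map
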