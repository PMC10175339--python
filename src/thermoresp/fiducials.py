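"""Colour-coded fiducial markers standing in for facial landmarks.

The synthetic visible stream does not render a face; instead each of the
five facial landmarks (eye centres, nose tip, mouth corners) is planted
as a small disk of a unique saturated colour on an otherwise grey scene.
The bundled landmark detector recovers them by colour masking, which
exercises the detection/tracking machinery without requiring a
pretrained face model.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray

__all__ = ["LANDMARK_NAMES", "FIDUCIAL_COLORS", "draw_fiducial",
           "find_fiducial", "DEFAULT_RADIUS"]

LANDMARK_NAMES = ("left_eye", "right_eye", "nose_tip", "mouth_left", "mouth_right")

# one saturated colour per landmark; the grey synthetic background can
# never reach these, so masking is unambiguous
FIDUCIAL_COLORS: dict[str, tuple[int, int, int]] = {
    "left_eye": (255, 0, 0),
    "right_eye": (0, 255, 0),
    "nose_tip": (0, 0, 255),
    "mouth_left": (255, 255, 0),
    "mouth_right": (255, 0, 255),
}

DEFAULT_RADIUS = 4


def draw_fiducial(frame: NDArray[np.uint8], center: tuple[float, float],
                  color: tuple[int, int, int], radius: int = DEFAULT_RADIUS) -> None:
    """Paint a filled disk (in place) at ``center`` = (x, y)."""
    h, w = frame.shape[:2]
    cx, cy = center
    x0 = max(0, int(np.floor(cx - radius)))
    x1 = min(w, int(np.ceil(cx + radius + 1)))
    y0 = max(0, int(np.floor(cy - radius)))
    y1 = min(h, int(np.ceil(cy + radius + 1)))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    frame[y0:y1, x0:x1][mask] = color


def find_fiducial(frame: NDArray[np.uint8], color: tuple[int, int, int],
                  radius: int = DEFAULT_RADIUS, tol: int = 60,
                  region: tuple[int, int, int, int] | None = None,
                  ) -> tuple[tuple[float, float] | None, float]:
    """Locate one colour-coded marker.

    Returns ``((x, y), confidence)`` where confidence is the visible
    fraction of the expected disk area (capped at 1), or ``(None, 0.0)``
    when no pixel matches.  ``region`` = (x0, y0, x1, y1) restricts the
    search window.
    """
    h, w = frame.shape[:2]
    if region is not None:
        x0, y0, x1, y1 = region
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(w, x1), min(h, y1)
    else:
        x0, y0, x1, y1 = 0, 0, w, h
    if x0 >= x1 or y0 >= y1:
        return None, 0.0
    sub = frame[y0:y1, x0:x1].astype(np.int16)
    dist = np.abs(sub - np.array(color, dtype=np.int16)).max(axis=-1)
    mask = dist < tol
    n = int(mask.sum())
    if n == 0:
        return None, 0.0
    ys, xs = np.nonzero(mask)
    cx = float(xs.mean()) + x0
    cy = float(ys.mean()) + y0
    expected = np.pi * radius**2
    confidence = min(1.0, n / expected)
    return (cx, cy), confidence
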