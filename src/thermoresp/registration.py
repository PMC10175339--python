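"""Two-phase visible-to-thermal registration.

Phase 1 (rig): a checkerboard calibration rig visible in both modalities
yields corresponding inner corners from which a similarity transform
(isotropic scale + translation; rotation optional) is fitted, removing
the large resolution disparity between the cameras.

Phase 2 (precise): phase congruency is computed on the roughly aligned
pair; FAST corners are detected on the maximum/minimum moment maps,
described by orientation-index histograms (a SIFT-like grid histogram
of the dominant log-Gabor orientation, which is stable across imaging
modalities), matched by SSD under a nearest-neighbour distance-ratio
test, and a fast-sample-consensus loop fits the refining affine map.
The composed map sends visible pixel coordinates to thermal pixel
coordinates and is held fixed for a recording (the cameras are rigidly
co-mounted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage
from skimage.feature import corner_fast, corner_peaks
from skimage.transform import AffineTransform, warp

from .errors import RegistrationError, RigNotFoundError
from .pc_features import (LogGaborBankParams, MomentMaps, OrientationIndexMap,
                          compute_pc_maps)
from .roi_tracking import ROIBox

__all__ = [
    "Keypoint",
    "Descriptor",
    "MatchSet",
    "AffineMap",
    "RegistrationParams",
    "detect_keypoints",
    "describe_keypoints",
    "match_descriptors",
    "estimate_affine_fsc",
    "find_checkerboard_corners",
    "scale_adjust_from_rig",
    "register_rgbt",
    "map_roi",
]

FloatArray = NDArray[np.floating]


# ---------------------------------------------------------------------------
# transform container


@dataclass(frozen=True)
class AffineMap:
    """2x3 affine map from visible pixel (x, y) to thermal pixel (x, y)."""

    matrix: FloatArray                  # shape (2, 3)
    inlier_count: int = 0
    rms_residual: float = 0.0
    provenance: str = "precise"         # rig | precise | composed

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) <= 1e-8:
            raise RegistrationError("affine map is (near-)singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, provenance: str = "rig") -> "AffineMap":
        return cls(matrix=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
                   provenance=provenance)

    @classmethod
    def from_similarity(cls, scale: float, tx: float, ty: float,
                        rotation: float = 0.0, provenance: str = "rig",
                        **kw) -> "AffineMap":
        c, s = np.cos(rotation), np.sin(rotation)
        m = np.array([[scale * c, -scale * s, tx],
                      [scale * s, scale * c, ty]])
        return cls(matrix=m, provenance=provenance, **kw)

    def as_3x3(self) -> FloatArray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def apply(self, points: FloatArray) -> FloatArray:
        """Map (N, 2) points given as (x, y) rows."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.as_3x3())
        return replace(self, matrix=inv[:2, :])

    def compose(self, inner: "AffineMap", provenance: str = "composed") -> "AffineMap":
        """Map applying ``inner`` first, then ``self``."""
        m = self.as_3x3() @ inner.as_3x3()
        return AffineMap(matrix=m[:2, :], inlier_count=self.inlier_count,
                         rms_residual=self.rms_residual, provenance=provenance)

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "provenance": self.provenance,
                "inlier_count": int(self.inlier_count),
                "rms_residual": float(self.rms_residual)}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineMap":
        return cls(matrix=np.asarray(d["matrix"], dtype=float),
                   inlier_count=int(d.get("inlier_count", 0)),
                   rms_residual=float(d.get("rms_residual", 0.0)),
                   provenance=d.get("provenance", "precise"))


# ---------------------------------------------------------------------------
# keypoints and descriptors


@dataclass(frozen=True)
class Keypoint:
    x: float
    y: float
    source: str      # "maximum" | "minimum" moment map
    score: float


@dataclass(frozen=True)
class Descriptor:
    vector: FloatArray
    keypoint: Keypoint


@dataclass(frozen=True)
class MatchSet:
    pairs: list[tuple[int, int, float]]   # (index_a, index_b, ssd)
    nndr_threshold: float

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RegistrationParams:
    """Tunables of the precise registration phase."""

    bank: LogGaborBankParams = field(default_factory=LogGaborBankParams)
    fast_threshold: float = 0.05
    max_keypoints: int = 500
    patch_size: int = 72
    descriptor_grid: int = 6
    nndr: float = 0.85
    fsc_iterations: int = 2000
    inlier_tol: float = 2.0
    seed: int = 0


def _minmax(img: FloatArray) -> FloatArray:
    lo, hi = float(np.min(img)), float(np.max(img))
    if hi - lo <= 0:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def detect_keypoints(moments: MomentMaps, fast_threshold: float = 0.05,
                     max_points: int = 500) -> list[Keypoint]:
    """FAST corners (arc of 12 on the 16-pixel circle) on M and m maps.

    Both maps are min-max normalised first so the detector threshold is
    comparable across images; non-maximum suppression keeps local peaks
    and the strongest ``max_points`` responses are returned.
    """
    kps: list[Keypoint] = []
    for source, img in (("maximum", moments.M), ("minimum", moments.m)):
        if not np.all(np.isfinite(img)):
            raise ValueError("non-finite values in moment map")
        norm = _minmax(img)
        resp = corner_fast(norm, n=12, threshold=fast_threshold)
        coords = corner_peaks(resp, min_distance=3, threshold_rel=0.0)
        for r, c in coords:
            kps.append(Keypoint(x=float(c), y=float(r), source=source,
                                score=float(resp[r, c])))
    kps.sort(key=lambda k: -k.score)
    return kps[:max_points]


def describe_keypoints(oim: OrientationIndexMap, kps: list[Keypoint],
                       patch_size: int = 72, grid: int = 6) -> list[Descriptor]:
    """SIFT-like grid histograms of the dominant-orientation index.

    The ``patch_size`` x ``patch_size`` patch around each keypoint is
    split into ``grid`` x ``grid`` cells; each cell contributes an
    ``N_o``-bin histogram of the 1-based orientation indices; the
    concatenation is L2-normalised.  Keypoints whose patch leaves the
    image are dropped.
    """
    if patch_size % grid != 0:
        raise ValueError("patch_size must be a multiple of grid")
    half = patch_size // 2
    cell = patch_size // grid
    index = oim.index
    h, w = index.shape
    n_o = oim.n_orientations
    out: list[Descriptor] = []
    for kp in kps:
        cx, cy = int(round(kp.x)), int(round(kp.y))
        if cx - half < 0 or cy - half < 0 or cx + half > w or cy + half > h:
            continue
        patch = index[cy - half:cy + half, cx - half:cx + half]
        cells = patch.reshape(grid, cell, grid, cell).transpose(0, 2, 1, 3)
        cells = cells.reshape(grid * grid, cell * cell)
        hist = np.zeros((grid * grid, n_o))
        for b in range(n_o):
            hist[:, b] = np.sum(cells == b + 1, axis=1)
        vec = hist.ravel().astype(float)
        norm = np.linalg.norm(vec)
        if norm == 0:
            continue
        out.append(Descriptor(vector=vec / norm, keypoint=kp))
    return out


def match_descriptors(a: list[Descriptor], b: list[Descriptor],
                      nndr: float = 0.85) -> MatchSet:
    """SSD matching with a nearest-neighbour distance-ratio test.

    A match is kept when ``d1 <= nndr * d2`` (so ``nndr = 1`` disables
    ratio pruning) and is mutually the best in both directions, which
    enforces a one-to-one assignment.
    """
    if not 0 < nndr <= 1:
        raise ValueError("nndr must be in (0, 1]")
    if len(a) < 2 or len(b) < 2:
        return MatchSet(pairs=[], nndr_threshold=nndr)
    va = np.stack([d.vector for d in a])
    vb = np.stack([d.vector for d in b])
    # SSD via the expansion |a-b|^2 = |a|^2 + |b|^2 - 2 a.b
    ssd = (np.sum(va**2, axis=1)[:, None] + np.sum(vb**2, axis=1)[None, :]
           - 2.0 * va @ vb.T)
    np.maximum(ssd, 0.0, out=ssd)

    order = np.argsort(ssd, axis=1)
    best = order[:, 0]
    second = order[:, 1]
    d1 = ssd[np.arange(len(a)), best]
    d2 = ssd[np.arange(len(a)), second]
    keep = np.where(d2 > 0, d1 <= nndr * d2, d1 == 0)

    best_for_b = np.argmin(ssd, axis=0)
    pairs = [(int(i), int(best[i]), float(d1[i]))
             for i in range(len(a))
             if keep[i] and best_for_b[best[i]] == i]
    return MatchSet(pairs=pairs, nndr_threshold=nndr)


# ---------------------------------------------------------------------------
# fast sample consensus


def _fit_affine_lstsq(src: FloatArray, dst: FloatArray) -> FloatArray:
    """Least-squares 2x3 affine sending src (x,y) rows to dst rows."""
    n = len(src)
    design = np.hstack([src, np.ones((n, 1))])
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return sol.T  # (2, 3)


def _collinear(pts: FloatArray, tol: float = 1e-6) -> bool:
    a, b, c = pts[:3]
    area = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
    return area <= tol


def estimate_affine_fsc(matches: MatchSet, kps_a: list[Keypoint],
                        kps_b: list[Keypoint], iterations: int = 2000,
                        inlier_tol: float = 2.0, seed: int = 0) -> AffineMap:
    """Fast-sample-consensus affine fit on matched keypoints.

    Each trial samples 3 matches, fits an exact affine, then grows a
    consensus set by re-fitting on the inliers until the set stabilises;
    the result with the most inliers (ties: lowest RMS) wins, and the
    returned map is the least-squares fit over its final inlier set.
    Deterministic for a fixed ``seed``.
    """
    if len(matches) < 3:
        raise RegistrationError(
            f"need >= 3 matches for an affine fit, got {len(matches)}",
            stage="consensus")
    src = np.array([[kps_a[i].x, kps_a[i].y] for i, _, _ in matches.pairs])
    dst = np.array([[kps_b[j].x, kps_b[j].y] for _, j, _ in matches.pairs])
    n = len(src)
    rng = np.random.default_rng(seed)

    best_inliers: NDArray[np.bool_] | None = None
    best_rms = np.inf

    def residuals(mat: FloatArray) -> FloatArray:
        proj = src @ mat[:, :2].T + mat[:, 2]
        return np.linalg.norm(proj - dst, axis=1)

    n_trials = min(iterations, 1) if n == 3 else iterations
    for _ in range(n_trials):
        idx = rng.choice(n, size=3, replace=False) if n > 3 else np.arange(3)
        if _collinear(src[idx]) or _collinear(dst[idx]):
            continue
        mat = _fit_affine_lstsq(src[idx], dst[idx])
        inliers = residuals(mat) <= inlier_tol
        if inliers.sum() < 3:
            continue
        # consensus growth: refit on inliers until the set is stable
        for _ in range(20):
            mat = _fit_affine_lstsq(src[inliers], dst[inliers])
            new_inliers = residuals(mat) <= inlier_tol
            if np.array_equal(new_inliers, inliers):
                break
            inliers = new_inliers
            if inliers.sum() < 3:
                break
        n_in = int(inliers.sum())
        if n_in < 3:
            continue
        rms = float(np.sqrt(np.mean(residuals(mat)[inliers] ** 2)))
        n_best = 0 if best_inliers is None else int(best_inliers.sum())
        if n_in > n_best or (n_in == n_best and rms < best_rms):
            best_inliers, best_rms = inliers, rms
        if n_in == n:
            break

    if best_inliers is None:
        raise RegistrationError("no non-degenerate consensus set found",
                                stage="consensus")
    mat = _fit_affine_lstsq(src[best_inliers], dst[best_inliers])
    rms = float(np.sqrt(np.mean(residuals(mat)[best_inliers] ** 2)))
    return AffineMap(matrix=mat, inlier_count=int(best_inliers.sum()),
                     rms_residual=rms, provenance="precise")


# ---------------------------------------------------------------------------
# calibration rig


_XCORNER_KERNEL = np.array([[1.0, 1.0, -1.0, -1.0],
                            [1.0, 1.0, -1.0, -1.0],
                            [-1.0, -1.0, 1.0, 1.0],
                            [-1.0, -1.0, 1.0, 1.0]]) / 16.0


def _subpixel_peak(resp: FloatArray, r: int, c: int) -> tuple[float, float]:
    """Parabolic refinement of a response peak to sub-pixel accuracy."""
    def refine(v0, v1, v2):
        denom = v0 - 2 * v1 + v2
        if abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (v0 - v2) / denom, -0.5, 0.5))

    h, w = resp.shape
    dy = refine(resp[r - 1, c], resp[r, c], resp[r + 1, c]) if 0 < r < h - 1 else 0.0
    dx = refine(resp[r, c - 1], resp[r, c], resp[r, c + 1]) if 0 < c < w - 1 else 0.0
    return c + dx, r + dy


def find_checkerboard_corners(image: FloatArray, rows: int, cols: int,
                              ) -> FloatArray:
    """Inner corners of a checkerboard, ordered row-major, as (x, y) rows.

    Polarity-agnostic: the absolute response to a 2x2-quadrant kernel
    peaks at X-junctions regardless of which modality (or contrast
    inversion) rendered the board.  Assumes the board is close to
    axis-aligned (rotation of a few degrees at most).
    """
    gray = _to_gray_float(image)
    gray = _minmax(gray)
    smoothed = ndimage.gaussian_filter(gray, 1.0)
    resp = np.abs(ndimage.correlate(smoothed, _XCORNER_KERNEL, mode="nearest"))
    peaks = corner_peaks(resp, min_distance=4, threshold_rel=0.55,
                         num_peaks=rows * cols)
    if len(peaks) < rows * cols:
        raise RigNotFoundError(
            f"found {len(peaks)} checkerboard corners, expected {rows * cols}",
            modality="unknown")
    # the 4x4 kernel's true centre lies between pixels: correlate() pins
    # it half a pixel low-right, so shift the peaks back
    pts = np.array([_subpixel_peak(resp, r, c) for r, c in peaks]) - 0.5
    # order row-major: sort by y, chunk into rows, sort each row by x
    pts = pts[np.argsort(pts[:, 1], kind="stable")]
    ordered = []
    for i in range(rows):
        row = pts[i * cols:(i + 1) * cols]
        ordered.append(row[np.argsort(row[:, 0], kind="stable")])
    return np.vstack(ordered)


def _to_gray_float(image: NDArray) -> FloatArray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    return arr


def _fit_similarity(src: FloatArray, dst: FloatArray,
                    allow_rotation: bool = False) -> FloatArray:
    """Least-squares similarity (scale [+rotation] + translation), 2x3."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    cs = src - mu_s
    cd = dst - mu_d
    if allow_rotation:
        # Umeyama: rotation from the SVD of the cross-covariance
        cov = cd.T @ cs / len(src)
        u, s, vt = np.linalg.svd(cov)
        d = np.sign(np.linalg.det(u @ vt))
        S = np.diag([1.0, d])
        rot = u @ S @ vt
        var = np.mean(np.sum(cs**2, axis=1))
        scale = np.trace(np.diag(s) @ S) / var
        lin = scale * rot
    else:
        scale = float(np.sum(cs * cd) / np.sum(cs * cs))
        lin = scale * np.eye(2)
    t = mu_d - lin @ mu_s
    return np.hstack([lin, t[:, None]])


def scale_adjust_from_rig(rgb_frame: NDArray, thermal_frame: NDArray,
                          rig_spec: tuple[int, int],
                          allow_rotation: bool = False) -> AffineMap:
    """Similarity transform from checkerboard corners seen in both modalities.

    ``rig_spec`` = (rows, cols) of inner corners.  The thermal board has
    inverted contrast (the rig material is a poor heat conductor), which
    the polarity-agnostic corner finder absorbs.
    """
    rows, cols = rig_spec
    if rows < 3 or cols < 3 or rows * cols < 12:
        raise ValueError("rig must expose at least a 4x3 inner-corner grid")
    try:
        pts_rgb = find_checkerboard_corners(rgb_frame, rows, cols)
    except RigNotFoundError as exc:
        raise RigNotFoundError(f"rig not found in visible frame: {exc}",
                               modality="visible") from exc
    try:
        pts_th = find_checkerboard_corners(thermal_frame, rows, cols)
    except RigNotFoundError as exc:
        raise RigNotFoundError(f"rig not found in thermal frame: {exc}",
                               modality="thermal") from exc
    mat = _fit_similarity(pts_rgb, pts_th, allow_rotation=allow_rotation)
    proj = pts_rgb @ mat[:, :2].T + mat[:, 2]
    rms = float(np.sqrt(np.mean(np.sum((proj - pts_th) ** 2, axis=1))))
    return AffineMap(matrix=mat, inlier_count=len(pts_rgb), rms_residual=rms,
                     provenance="rig")


# ---------------------------------------------------------------------------
# full registration chain


def warp_to_thermal(rgb_frame: NDArray, rig_map: AffineMap,
                    thermal_shape: tuple[int, int]) -> FloatArray:
    """Resample the visible frame into (rough) thermal coordinates."""
    gray = _to_gray_float(rgb_frame)
    tform = AffineTransform(matrix=rig_map.inverse().as_3x3())
    return warp(gray, tform, output_shape=thermal_shape, mode="reflect",
                preserve_range=True)


def register_rgbt(rgb_frame: NDArray, thermal_frame: NDArray,
                  rig_map: AffineMap | None = None,
                  params: RegistrationParams | None = None) -> AffineMap:
    """Full precise-registration chain, composed with the rig map.

    The visible frame is first resampled into rough thermal coordinates
    through ``rig_map`` (identity if ``None``); phase congruency is
    computed on both images, FAST keypoints on the moment maps are
    described and matched, and fast sample consensus fits the refining
    affine.  The returned map has provenance ``"composed"`` and sends
    original visible pixels to thermal pixels.
    """
    params = params or RegistrationParams()
    if rig_map is None:
        rig_map = AffineMap.identity()
    thermal = _to_gray_float(thermal_frame)
    rough = warp_to_thermal(rgb_frame, rig_map, thermal.shape)

    # descriptor patches must leave keypoints inside small frames: cap
    # the patch at a third of the short side (largest grid multiple)
    grid = params.descriptor_grid
    max_patch = max(grid, (min(thermal.shape) // 3) // grid * grid)
    patch_size = min(params.patch_size, max_patch)

    descriptors = []
    keypoints = []
    for img in (rough, thermal):
        pc, moments, oim = compute_pc_maps(_minmax(img), params.bank)
        kps = detect_keypoints(moments, params.fast_threshold,
                               params.max_keypoints)
        if not kps:
            raise RegistrationError("no keypoints detected", stage="keypoints")
        desc = describe_keypoints(oim, kps, patch_size, grid)
        if not desc:
            raise RegistrationError("no describable keypoints (image too small "
                                    "for the descriptor patch)", stage="keypoints")
        keypoints.append([d.keypoint for d in desc])
        descriptors.append(desc)

    matches = match_descriptors(descriptors[0], descriptors[1], params.nndr)
    if len(matches) < 3:
        raise RegistrationError(f"only {len(matches)} descriptor matches",
                                stage="matching")
    precise = estimate_affine_fsc(matches, keypoints[0], keypoints[1],
                                  iterations=params.fsc_iterations,
                                  inlier_tol=params.inlier_tol,
                                  seed=params.seed)
    return precise.compose(rig_map, provenance="composed")


def map_roi(roi: ROIBox, amap: AffineMap,
            thermal_shape: tuple[int, int]) -> ROIBox:
    """Map a visible-frame ROI into the thermal frame.

    The four corners are mapped, the axis-aligned bounding box is taken,
    rounded outward to integer pixels and clipped; a box falling fully
    outside the thermal frame comes back with zero width/height
    (``valid`` is False).
    """
    pts = amap.apply(roi.corners())
    x0 = int(np.floor(pts[:, 0].min()))
    y0 = int(np.floor(pts[:, 1].min()))
    x1 = int(np.ceil(pts[:, 0].max()))
    y1 = int(np.ceil(pts[:, 1].max()))
    box = ROIBox(bx=x0, by=y0, w=x1 - x0, h=y1 - y0, frame_id=roi.frame_id,
                 coord_frame="thermal", eta=roi.eta, omega=roi.omega)
    return box.clipped(thermal_shape)
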