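"""Keypoints, descriptors, matching, consensus fitting, rig calibration."""

import numpy as np
import pytest

from thermoresp.errors import RegistrationError, RigNotFoundError
from thermoresp.pc_features import compute_pc_maps
from thermoresp.registration import (
    AffineMap,
    Descriptor,
    Keypoint,
    MatchSet,
    describe_keypoints,
    detect_keypoints,
    estimate_affine_fsc,
    find_checkerboard_corners,
    map_roi,
    match_descriptors,
    register_rgbt,
    scale_adjust_from_rig,
)
from thermoresp.roi_tracking import ROIBox
from thermoresp.synth import (
    generate_rig_pair,
    generate_structured_pair,
    rig_inner_corners_visible,
)


class TestAffineMap:
    def test_round_trip_inverse(self):
        amap = AffineMap.from_similarity(3.0, 12.0, -7.0,
                                         rotation=np.deg2rad(4))
        pts = np.array([[0.0, 0.0], [100.0, 50.0], [-3.0, 7.0]])
        back = amap.inverse().apply(amap.apply(pts))
        assert np.abs(back - pts).max() <= 1e-6

    def test_singular_rejected(self):
        with pytest.raises(RegistrationError):
            AffineMap(matrix=np.array([[1.0, 2.0, 0.0], [2.0, 4.0, 0.0]]))

    def test_json_round_trip(self):
        amap = AffineMap.from_similarity(0.5, 1.0, 2.0, provenance="rig")
        clone = AffineMap.from_dict(amap.to_dict())
        assert np.allclose(clone.matrix, amap.matrix)
        assert clone.provenance == "rig"

    def test_composition_order(self):
        inner = AffineMap.from_similarity(2.0, 1.0, 0.0)
        outer = AffineMap.from_similarity(1.0, 5.0, 5.0)
        composed = outer.compose(inner)
        pt = np.array([[1.0, 1.0]])
        assert np.allclose(composed.apply(pt), outer.apply(inner.apply(pt)))


class TestDetectKeypoints:
    def test_all_zero_maps_give_nothing(self):
        _, mom, _ = compute_pc_maps(np.zeros((64, 64)))
        assert detect_keypoints(mom) == []

    def test_bright_square_corners_found(self):
        img = np.zeros((80, 80))
        img[30:50, 30:50] = 1.0
        _, mom, _ = compute_pc_maps(img)
        kps = detect_keypoints(mom, max_points=50)
        assert kps
        for cx, cy in [(29.5, 29.5), (49.5, 29.5), (29.5, 49.5), (49.5, 49.5)]:
            d = min(np.hypot(k.x - cx, k.y - cy) for k in kps)
            assert d <= 2.0

    def test_truncation_to_max_points(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(96, 96)).cumsum(axis=0).cumsum(axis=1)
        _, mom, _ = compute_pc_maps(img)
        assert len(detect_keypoints(mom, max_points=5)) <= 5


@pytest.fixture(scope="module")
def scene():
    rng = np.random.default_rng(6)
    img = np.full((128, 128), 0.5)
    for _ in range(15):
        x0, y0 = rng.integers(0, 90, 2)
        img[y0:y0 + rng.integers(10, 35), x0:x0 + rng.integers(10, 35)] = \
            rng.uniform(0, 1)
    return img


class TestDescriptors:
    def test_identical_patches_identical_descriptors(self, scene):
        _, mom, oim = compute_pc_maps(scene)
        kps = detect_keypoints(mom, max_points=30)
        desc = describe_keypoints(oim, kps, patch_size=48, grid=6)
        assert desc
        d0 = desc[0]
        again = describe_keypoints(oim, [d0.keypoint], patch_size=48, grid=6)[0]
        assert float(np.sum((d0.vector - again.vector) ** 2)) == 0.0

    def test_intensity_scaling_preserves_descriptors(self, scene):
        _, mom, oim1 = compute_pc_maps(scene)
        _, _, oim2 = compute_pc_maps(2.0 * scene)
        kps = detect_keypoints(mom, max_points=20)
        d1 = describe_keypoints(oim1, kps, patch_size=48, grid=6)
        d2 = describe_keypoints(oim2, kps, patch_size=48, grid=6)
        for a, b in zip(d1, d2):
            assert np.allclose(a.vector, b.vector)

    def test_descriptor_length_and_norm(self, scene):
        _, mom, oim = compute_pc_maps(scene)
        kps = detect_keypoints(mom, max_points=30)
        desc = describe_keypoints(oim, kps, patch_size=48, grid=6)
        for d in desc:
            assert len(d.vector) == 36 * oim.n_orientations
            assert abs(np.linalg.norm(d.vector) - 1.0) <= 1e-12

    def test_patch_must_divide_grid(self, scene):
        _, mom, oim = compute_pc_maps(scene)
        with pytest.raises(ValueError):
            describe_keypoints(oim, [], patch_size=50, grid=6)


def _make_descriptors(vectors):
    return [Descriptor(vector=np.asarray(v, dtype=float),
                       keypoint=Keypoint(i, i, "maximum", 1.0))
            for i, v in enumerate(vectors)]


class TestMatching:
    def test_self_match_ssd_zero(self):
        rng = np.random.default_rng(7)
        vecs = rng.uniform(0, 1, size=(10, 16))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        a = _make_descriptors(vecs)
        b = _make_descriptors(vecs)
        ms = match_descriptors(a, b, nndr=0.8)
        assert len(ms) == 10
        for i, j, ssd in ms.pairs:
            assert i == j
            assert ssd <= 1e-12

    def test_nndr_one_keeps_all_nearest(self):
        rng = np.random.default_rng(8)
        vecs = rng.uniform(0, 1, size=(6, 8))
        a = _make_descriptors(vecs + 0.01)
        b = _make_descriptors(vecs)
        ms = match_descriptors(a, b, nndr=1.0)
        assert len(ms) == 6

    def test_planted_pairs_recovered_among_decoys(self):
        rng = np.random.default_rng(9)
        true = rng.uniform(0, 1, size=(30, 24))
        true /= np.linalg.norm(true, axis=1, keepdims=True)
        decoys = rng.uniform(0, 1, size=(10, 24))
        decoys /= np.linalg.norm(decoys, axis=1, keepdims=True)
        a = _make_descriptors(true)
        b = _make_descriptors(np.vstack([true + rng.normal(0, 0.01, true.shape),
                                         decoys]))
        ms = match_descriptors(a, b, nndr=0.8)
        correct = sum(1 for i, j, _ in ms.pairs if i == j)
        assert correct >= 25

    def test_too_few_candidates_empty(self):
        a = _make_descriptors(np.eye(3))
        assert len(match_descriptors(a, a[:1], nndr=0.8)) == 0
        assert len(match_descriptors(a[:1], a, nndr=0.8)) == 0


class TestFSC:
    def _correspondences(self, n, amap, seed=0, jitter=0.0):
        rng = np.random.default_rng(seed)
        src = rng.uniform(0, 300, size=(n, 2))
        dst = amap.apply(src) + rng.normal(0, jitter, size=(n, 2))
        ka = [Keypoint(x, y, "maximum", 1.0) for x, y in src]
        kb = [Keypoint(x, y, "maximum", 1.0) for x, y in dst]
        ms = MatchSet(pairs=[(i, i, 0.0) for i in range(n)], nndr_threshold=0.8)
        return ms, ka, kb

    def test_exact_recovery(self):
        true = AffineMap.from_similarity(3.0, 12.0, -7.0,
                                         rotation=np.deg2rad(4))
        ms, ka, kb = self._correspondences(50, true, seed=1)
        est = estimate_affine_fsc(ms, ka, kb, seed=3)
        assert np.abs(est.matrix - true.matrix).max() <= 1e-6
        assert est.inlier_count == 50

    def test_robust_to_gross_outliers(self):
        true = AffineMap.from_similarity(3.0, 12.0, -7.0,
                                         rotation=np.deg2rad(4))
        ms, ka, kb = self._correspondences(50, true, seed=2)
        rng = np.random.default_rng(5)
        for i in rng.choice(50, size=10, replace=False):
            kb[i] = Keypoint(*rng.uniform(0, 300, 2), "maximum", 1.0)
        est = estimate_affine_fsc(ms, ka, kb, inlier_tol=2.0, seed=4)
        corners = np.array([[0, 0], [300, 0], [0, 300], [300, 300]], float)
        err = np.linalg.norm(est.apply(corners) - true.apply(corners),
                             axis=1).mean()
        assert err <= 0.5

    def test_identity_correspondences(self):
        ident = AffineMap.identity()
        ms, ka, kb = self._correspondences(10, ident, seed=3)
        est = estimate_affine_fsc(ms, ka, kb, seed=0)
        assert np.abs(est.matrix - ident.matrix).max() <= 1e-9
        assert est.rms_residual <= 1e-9

    def test_deterministic_given_seed(self):
        true = AffineMap.from_similarity(2.0, 5.0, 5.0)
        ms, ka, kb = self._correspondences(40, true, seed=4, jitter=0.5)
        m1 = estimate_affine_fsc(ms, ka, kb, seed=11)
        m2 = estimate_affine_fsc(ms, ka, kb, seed=11)
        assert np.array_equal(m1.matrix, m2.matrix)

    def test_too_few_matches_fails(self):
        ms = MatchSet(pairs=[(0, 0, 0.0)], nndr_threshold=0.8)
        with pytest.raises(RegistrationError):
            estimate_affine_fsc(ms, [Keypoint(0, 0, "maximum", 1)],
                                [Keypoint(0, 0, "maximum", 1)])


class TestRigCalibration:
    def test_corner_recovery_closed_loop(self):
        rgb, thermal, _ = generate_rig_pair()
        detected = find_checkerboard_corners(rgb, 5, 6)
        truth = rig_inner_corners_visible()
        rms = np.sqrt(np.mean(np.sum((detected - truth) ** 2, axis=1)))
        assert rms <= 0.5

    def test_scale_and_translation_recovered(self):
        true_map = AffineMap.from_similarity(1.0 / 3.0, 10.0 / 3.0, 5.0 / 3.0)
        rgb, thermal, _ = generate_rig_pair(true_map=true_map)
        rig = scale_adjust_from_rig(rgb, thermal, (5, 6))
        scale = float(np.sqrt(abs(np.linalg.det(rig.matrix[:, :2]))))
        assert abs(scale - 1.0 / 3.0) <= 0.01 / 3.0
        assert np.abs(rig.matrix[:, 2] - true_map.matrix[:, 2]).max() <= 0.5

    def test_identical_frames_identity(self):
        rgb, _, _ = generate_rig_pair(true_map=AffineMap.identity(),
                                      thermal_shape=(720, 960))
        gray = rgb[:, :, 0].astype(float)
        rig = scale_adjust_from_rig(gray, gray, (5, 6))
        assert np.abs(rig.matrix - AffineMap.identity().matrix).max() <= 0.05

    def test_rig_absent_names_modality(self):
        blank = np.full((240, 320), 30.0)
        rgb, _, _ = generate_rig_pair()
        with pytest.raises(RigNotFoundError) as exc:
            scale_adjust_from_rig(rgb, blank, (5, 6))
        assert exc.value.modality == "thermal"


class TestRegisterRgbt:
    def test_known_similarity_recovered(self):
        rgb, thermal, true_map = generate_structured_pair(
            seed=7, scale=3.0, rotation_deg=3.0, translation=(8.0, -5.0))
        rig_rgb, rig_th, _ = generate_rig_pair(true_map=true_map)
        rig = scale_adjust_from_rig(rig_rgb, rig_th, (5, 6))
        composed = register_rgbt(rgb, thermal, rig)
        corners = np.array([[0, 0], [959, 0], [0, 719], [959, 719]], float)
        err = np.linalg.norm(composed.apply(corners)
                             - true_map.apply(corners), axis=1).mean()
        assert err <= 2.0
        assert composed.provenance == "composed"

    def test_self_registration_near_identity(self):
        rgb, thermal, _ = generate_structured_pair(
            seed=8, scale=1.0, rotation_deg=0.0,
            rgb_shape=(240, 320), thermal_shape=(240, 320))
        composed = register_rgbt(thermal, thermal, AffineMap.identity())
        corners = np.array([[0, 0], [319, 0], [0, 239], [319, 239]], float)
        err = np.linalg.norm(composed.apply(corners) - corners, axis=1).mean()
        assert err <= 0.5

    def test_featureless_pair_fails_at_keypoints(self):
        flat = np.full((240, 320), 0.5)
        with pytest.raises(RegistrationError) as exc:
            register_rgbt(flat, flat, AffineMap.identity())
        assert exc.value.stage == "keypoints"


class TestMapRoi:
    def test_identity_map_same_box(self):
        roi = ROIBox(bx=10, by=20, w=30, h=40)
        out = map_roi(roi, AffineMap.identity(), (240, 320))
        assert (out.bx, out.by, out.w, out.h) == (10, 20, 30, 40)
        assert out.coord_frame == "thermal"

    def test_third_scale_outward_rounding(self):
        roi = ROIBox(bx=90, by=94, w=20, h=18)
        amap = AffineMap.from_similarity(1.0 / 3.0, 0.0, 0.0)
        out = map_roi(roi, amap, (240, 320))
        assert (out.bx, out.by, out.w, out.h) == (30, 31, 7, 7)

    def test_fully_outside_box_is_flagged_empty(self):
        roi = ROIBox(bx=10, by=10, w=5, h=5)
        amap = AffineMap.from_similarity(1.0, 1000.0, 1000.0)
        out = map_roi(roi, amap, (240, 320))
        assert not out.valid

    def test_inverse_round_trip_contains_original(self):
        rng = np.random.default_rng(10)
        amap = AffineMap.from_similarity(1.0 / 3.0, 4.0, -2.0,
                                         rotation=np.deg2rad(2))
        for _ in range(20):
            bx, by = rng.integers(30, 400, 2)
            w, h = rng.integers(5, 60, 2)
            roi = ROIBox(bx=int(bx), by=int(by), w=int(w), h=int(h))
            fwd = map_roi(roi, amap, (10_000, 10_000))
            back = map_roi(fwd, amap.inverse(), (20_000, 20_000))
            assert back.bx <= roi.bx and back.by <= roi.by
            assert back.bx + back.w >= roi.bx + roi.w
            assert back.by + back.h >= roi.by + roi.h
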