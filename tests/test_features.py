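import math

import numpy as np
import pandas as pd
import pytest

from longlie import (BodySegments, CANONICAL_KEYPOINTS, Keypoint, PoseFrame,
                     acb_angle, compute_whr, frame_features, hip_center,
                     orientation_angles, segment_cog, zscore_apply, zscore_fit)
from longlie.features import FeatureUndefined, angle_from_vertical

from oracles import vertex_angle_oracle, vertical_angle_oracle, whr_oracle


def frame_with(points: dict) -> PoseFrame:
    kps = {n: None for n in CANONICAL_KEYPOINTS}
    for name, (x, y) in points.items():
        kps[name] = Keypoint(x, y, 1.0)
    return PoseFrame(0, kps)


class TestWHR:
    def test_upright_configuration(self):
        f = frame_with({"shoulder_l": (0.2, 0.2), "shoulder_r": (0.6, 0.2),
                        "knee_l": (0.25, 0.9), "knee_r": (0.55, 0.9)})
        assert compute_whr(f) == pytest.approx(0.4 / 0.7)

    def test_lying_configuration(self):
        f = frame_with({"shoulder_l": (0.1, 0.50), "shoulder_r": (0.15, 0.60),
                        "knee_l": (0.80, 0.55), "knee_r": (0.75, 0.62)})
        assert compute_whr(f) == pytest.approx(0.7 / 0.12)

    def test_square_extent_gives_one(self):
        f = frame_with({"shoulder_l": (0.2, 0.2), "shoulder_r": (0.5, 0.2),
                        "knee_l": (0.2, 0.5), "knee_r": (0.5, 0.5)})
        assert compute_whr(f) == pytest.approx(1.0)

    def test_single_shoulder_and_knee_suffice(self):
        f = frame_with({"shoulder_l": (0.2, 0.2), "knee_r": (0.5, 0.6)})
        assert compute_whr(f) == pytest.approx(0.3 / 0.4)

    def test_missing_all_knees_undefined(self):
        f = frame_with({"shoulder_l": (0.2, 0.2), "shoulder_r": (0.6, 0.2)})
        with pytest.raises(FeatureUndefined):
            compute_whr(f)

    def test_zero_height_undefined(self):
        f = frame_with({"shoulder_l": (0.2, 0.5), "knee_l": (0.6, 0.5)})
        with pytest.raises(FeatureUndefined):
            compute_whr(f)


class TestCOG:
    def test_uniform_weights_centroid(self):
        f = frame_with({"hip_l": (0.0, 0.0), "hip_r": (2.0 / 3, 0.0),
                        "knee_l": (1.0 / 3, 1.0)})
        cog = segment_cog(f, ("hip_l", "hip_r", "knee_l"))
        assert cog == pytest.approx((1.0 / 3, 1.0 / 3))

    def test_single_point(self):
        f = frame_with({"hip_l": (0.3, 0.7)})
        assert segment_cog(f, ("hip_l", "hip_r")) == pytest.approx((0.3, 0.7))

    def test_weighted_mean(self):
        f = frame_with({"hip_l": (0.0, 0.0), "hip_r": (0.4, 0.0)})
        cog = segment_cog(f, ("hip_l", "hip_r"),
                          weights={"hip_l": 1.0, "hip_r": 3.0})
        assert cog == pytest.approx((0.3, 0.0))

    def test_empty_segment_undefined(self):
        f = frame_with({"nose": (0.5, 0.1)})
        with pytest.raises(FeatureUndefined):
            segment_cog(f, ("hip_l", "hip_r"))


class TestOrientationAngles:
    def test_vertical_body_scores_zero(self):
        # COGs stacked vertically: upper above whole above lower
        assert angle_from_vertical((0.5, 0.2), (0.5, 0.5)) == pytest.approx(0.0)

    def test_horizontal_body_scores_half_pi(self):
        assert angle_from_vertical((0.8, 0.5), (0.5, 0.5)) == pytest.approx(math.pi / 2)
        assert angle_from_vertical((0.2, 0.5), (0.5, 0.5)) == pytest.approx(math.pi / 2)

    def test_45_degree_geometry(self):
        assert angle_from_vertical((0.7, 0.3), (0.5, 0.5)) == pytest.approx(math.pi / 4)

    def test_coincident_cogs_undefined(self):
        with pytest.raises(FeatureUndefined):
            angle_from_vertical((0.5, 0.5), (0.5, 0.5))

    def test_all_three_angles_on_a_straight_vertical_frame(self):
        f = frame_with({"nose": (0.5, 0.1), "shoulder_l": (0.45, 0.2),
                        "shoulder_r": (0.55, 0.2), "hip_l": (0.45, 0.5),
                        "hip_r": (0.55, 0.5), "knee_l": (0.45, 0.7),
                        "knee_r": (0.55, 0.7), "ankle_l": (0.45, 0.9),
                        "ankle_r": (0.55, 0.9)})
        t1, t2, t3 = orientation_angles(f)
        assert (t1, t2, t3) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)


class TestHipCenterAndACB:
    def test_hip_center_midpoint(self):
        f = frame_with({"hip_l": (0.4, 0.5), "hip_r": (0.6, 0.5)})
        assert hip_center(f) == pytest.approx((0.5, 0.5))

    def test_hip_center_general(self):
        f = frame_with({"hip_l": (0.3, 0.5), "hip_r": (0.5, 0.7)})
        assert hip_center(f) == pytest.approx((0.4, 0.6))

    def test_hip_center_missing_hip_undefined(self):
        f = frame_with({"hip_l": (0.3, 0.5)})
        with pytest.raises(FeatureUndefined):
            hip_center(f)

    def test_collinear_interior_vertex_gives_pi(self):
        assert acb_angle((0.0, 0.0), (1.0, 0.0), (2.0, 0.0)) == pytest.approx(math.pi)

    def test_right_angle(self):
        assert acb_angle((0.0, 0.0), (0.0, 1.0), (1.0, 1.0)) == pytest.approx(math.pi / 2)

    def test_symmetric_in_endpoints(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c = (tuple(rng.uniform(0, 1, 2)) for _ in range(3))
            assert acb_angle(a, b, c) == pytest.approx(acb_angle(c, b, a))

    def test_degenerate_vertex_undefined(self):
        with pytest.raises(FeatureUndefined):
            acb_angle((0.5, 0.5), (0.5, 0.5), (0.1, 0.1))


class TestFrameFeatures:
    def test_missing_knees_makes_frame_undefined(self):
        f = frame_with({n: (0.5, 0.1 * i) for i, n in enumerate(CANONICAL_KEYPOINTS)
                        if not n.startswith("knee")})
        assert not frame_features(f).defined

    def test_acb_degree_accessor(self):
        from longlie import FrameFeatures
        ff = FrameFeatures(1.0, 0.0, 0.0, 0.0, math.pi)
        assert ff.acb_degrees == pytest.approx(180.0)


class TestInvariances:
    def random_frame(self, rng):
        return frame_with({n: tuple(rng.uniform(0.1, 0.9, 2))
                           for n in CANONICAL_KEYPOINTS})

    def shifted(self, f, dx, dy, scale=1.0):
        pts = {n: (kp.x * scale + dx, kp.y * scale + dy)
               for n, kp in f.keypoints.items()}
        return frame_with(pts)

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            f = self.random_frame(rng)
            g = self.shifted(f, 3.7, -1.2)
            assert frame_features(g).as_tuple() == pytest.approx(
                frame_features(f).as_tuple(), abs=1e-9)

    def test_isotropic_scale_invariance(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            f = self.random_frame(rng)
            g = self.shifted(f, 0.0, 0.0, scale=4.5)
            assert frame_features(g).as_tuple() == pytest.approx(
                frame_features(f).as_tuple(), abs=1e-9)

    def test_angles_agree_with_arccos_oracle(self):
        rng = np.random.default_rng(13)
        segs = BodySegments()
        for _ in range(200):
            f = self.random_frame(rng)
            cub = segment_cog(f, segs.upper)
            clb = segment_cog(f, segs.lower)
            cwb = segment_cog(f, segs.whole)
            t1, t2, t3 = orientation_angles(f, segs)
            assert t1 == pytest.approx(vertical_angle_oracle(cub, cwb), abs=1e-9)
            assert t2 == pytest.approx(vertical_angle_oracle(cub, clb), abs=1e-9)
            assert t3 == pytest.approx(vertical_angle_oracle(cwb, clb), abs=1e-9)
            acb = acb_angle(cub, hip_center(f), clb)
            assert acb == pytest.approx(
                vertex_angle_oracle(cub, hip_center(f), clb), abs=1e-9)
            pts = [(f.keypoints[n].x, f.keypoints[n].y)
                   for n in ("shoulder_l", "shoulder_r", "knee_l", "knee_r")]
            assert compute_whr(f) == pytest.approx(whr_oracle(pts), abs=1e-9)


class TestZScore:
    def test_fit_apply_standardizes_training_data(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(3.0, 2.0, size=(50, 4)),
                             columns=list("abcd"))
        model = zscore_fit(table)
        z = zscore_apply(model, table)
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0) - 1).max() < 1e-9

    def test_constant_column_rejected_by_name(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="b"):
            zscore_fit(table)

    def test_heldout_apply_reuses_training_statistics(self):
        rng = np.random.default_rng(6)
        train = pd.DataFrame(rng.normal(0, 1, (40, 2)), columns=["a", "b"])
        held = pd.DataFrame(rng.normal(5, 1, (40, 2)), columns=["a", "b"])
        model = zscore_fit(train)
        z = zscore_apply(model, held)
        assert z.mean(axis=0).min() > 2.0  # shifted data stays shifted
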