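import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stereokit import denoise
from stereokit.types import FrameDetections, RawSkeleton, L_HIP, NECK, R_HIP


def make_raw(detected_xy, image_size=(656, 368)):
    """Build an 18-joint RawSkeleton from {coco_index: (x, y)}; rest undetected."""
    joints = np.zeros((18, 3))
    for j, (x, y) in detected_xy.items():
        joints[j] = (x, y, 1.0)
    return RawSkeleton(joints)


def full_raw(rng=None, image_size=(656, 368)):
    rng = rng or np.random.default_rng(0)
    w, h = image_size
    joints = np.column_stack([
        rng.uniform(0, w, 18), rng.uniform(0, h, 18), rng.uniform(0.5, 1, 18)
    ])
    return RawSkeleton(joints)


class TestScaleCoordinates:
    def test_divides_both_axes_by_height(self):
        s = make_raw({1: (328.0, 184.0)})
        out = denoise.scale_coordinates(s, (656, 368))
        np.testing.assert_allclose(out.joints[1, :2], [328 / 368, 0.5])

    def test_undetected_joint_untouched(self):
        s = make_raw({1: (328.0, 184.0)})
        out = denoise.scale_coordinates(s, (656, 368))
        np.testing.assert_array_equal(out.joints[0], [0, 0, 0])

    def test_zero_height_rejected(self):
        with pytest.raises(ValueError):
            denoise.scale_coordinates(make_raw({}), (656, 0))

    @given(st.integers(0, 17), st.integers(0, 17), st.data())
    @settings(max_examples=50, deadline=None)
    def test_distances_isotropic(self, j1, j2, data):
        # pixel distance / h equals scaled distance for any joint pair
        xs = data.draw(st.lists(st.floats(0, 656), min_size=4, max_size=4))
        ys = data.draw(st.lists(st.floats(0, 368), min_size=4, max_size=4))
        s = make_raw({j1: (xs[0], ys[0]), j2: (xs[1], ys[1])})
        out = denoise.scale_coordinates(s, (656, 368))
        d_px = np.linalg.norm(s.joints[j1, :2] - s.joints[j2, :2])
        d_scaled = np.linalg.norm(out.joints[j1, :2] - out.joints[j2, :2])
        assert d_scaled == pytest.approx(d_px / 368, abs=1e-9)


class TestRemoveHeadJoints:
    def test_maps_18_to_13_with_neck_first(self):
        s = full_raw()
        out = denoise.remove_head_joints(s)
        assert out.shape == (13, 3)
        np.testing.assert_array_equal(out[0], s.joints[1])  # Neck becomes joint 0

    def test_head_coordinates_absent(self):
        s = full_raw()
        out = denoise.remove_head_joints(s)
        head = s.joints[[0, 14, 15, 16, 17], :2]
        for row in head:
            assert not any(np.allclose(row, o) for o in out[:, :2])

    def test_wrong_joint_count_rejected(self):
        bad = RawSkeleton(np.zeros((18, 3)))
        bad.joints = np.zeros((17, 3))
        with pytest.raises(ValueError):
            denoise.remove_head_joints(bad)


class TestIsValidFrame:
    @pytest.mark.parametrize("neck,rhip,lhip", [
        (n, r, l) for n in (0, 1) for r in (0, 1) for l in (0, 1)
    ])
    def test_rule_enumerated(self, neck, rhip, lhip):
        body = np.zeros((13, 3))
        body[NECK, 2] = neck
        body[R_HIP, 2] = rhip
        body[L_HIP, 2] = lhip
        assert denoise.is_valid_frame(body) == bool(neck and (rhip or lhip))

    def test_missing_wrist_retained(self):
        body = np.ones((13, 3))
        body[3] = 0  # RWrist gone
        assert denoise.is_valid_frame(body)


def _oracle_fill(frames):
    """Independent loop oracle for the neck-relative imputation rule."""
    prev = None
    out = []
    for body in frames:
        coords = body[:, :2].copy()
        neck = coords[NECK].copy()
        for j in range(13):
            if body[j, 2] <= 0:
                if prev is None:
                    coords[j] = neck
                else:
                    coords[j] = neck + (prev[j] - prev[NECK])
        out.append(coords)
        prev = coords
    return out


class TestFillMissingJoints:
    def test_worked_example(self):
        prev = np.zeros((13, 3))
        prev[NECK] = (0.50, 0.40, 1)
        prev[3] = (0.62, 0.55, 1)  # RWrist
        curr = np.zeros((13, 3))
        curr[NECK] = (0.53, 0.41, 1)
        out = denoise.fill_missing_joints([prev, curr])
        np.testing.assert_allclose(out[1].joints[3], [0.65, 0.56])
        assert not out[1].valid[3]

    def test_observed_joints_unchanged(self):
        rng = np.random.default_rng(1)
        frames = [np.column_stack([rng.uniform(0, 1, (13,)), rng.uniform(0, 1, 13),
                                   np.ones(13)]) for _ in range(4)]
        out = denoise.fill_missing_joints([f.copy() for f in frames])
        for f, o in zip(frames, out):
            np.testing.assert_array_equal(o.joints, f[:, :2])
            assert o.valid.all()

    def test_constant_offset_across_k_missing_frames(self):
        rng = np.random.default_rng(2)
        frames = []
        for t in range(6):
            body = np.column_stack([rng.uniform(0, 1, 13), rng.uniform(0, 1, 13),
                                    np.ones(13)])
            if t >= 1:
                body[5, 2] = 0  # LElbow missing from frame 1 on
            frames.append(body)
        out = denoise.fill_missing_joints(frames)
        offsets = [o.joints[5] - o.joints[NECK] for o in out]
        for off in offsets[1:]:
            np.testing.assert_allclose(off, offsets[0], atol=1e-12)

    def test_matches_loop_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            frames = []
            for t in range(int(rng.integers(1, 8))):
                body = np.column_stack([
                    rng.uniform(0, 1.5, 13), rng.uniform(0, 1, 13),
                    (rng.random(13) > 0.3).astype(float),
                ])
                body[NECK, 2] = 1.0
                frames.append(body)
            expected = _oracle_fill(frames)
            out = denoise.fill_missing_joints(frames)
            for e, o in zip(expected, out):
                np.testing.assert_allclose(o.joints, e, atol=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            denoise.fill_missing_joints([])


def frames_from_raw(raws, image_size=(656, 368)):
    return [FrameDetections(t, image_size, [r]) for t, r in enumerate(raws)]


class TestDenoiseSequence:
    def test_neckless_frame_dropped_indices_preserved(self):
        rng = np.random.default_rng(4)
        raws = [full_raw(rng) for _ in range(5)]
        raws[3].joints[1] = 0.0  # no Neck in frame 3
        out = denoise.denoise_sequence(frames_from_raw(raws))
        assert [s.frame_index for s in out] == [0, 1, 2, 4]

    def test_fully_detected_is_scaled_reindexed_input(self):
        rng = np.random.default_rng(5)
        raws = [full_raw(rng) for _ in range(4)]
        out = denoise.denoise_sequence(frames_from_raw(raws))
        assert all(s.valid.all() for s in out)
        expected = raws[0].joints[[1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13], :2] / 368
        np.testing.assert_allclose(out[0].joints, expected)

    def test_dropout_leaves_no_missing_values(self):
        rng = np.random.default_rng(6)
        raws = []
        for _ in range(50):
            r = full_raw(rng)
            drop = rng.random(18) < 0.2
            r.joints[drop] = 0.0
            raws.append(r)
        out = denoise.denoise_sequence(frames_from_raw(raws))
        assert out, "some frames must survive"
        for s in out:
            assert np.isfinite(s.joints).all()
            assert s.valid[NECK]

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(7)
        raws = []
        for _ in range(10):
            r = full_raw(rng)
            drop = rng.random(18) < 0.25
            r.joints[drop] = 0.0
            raws.append(r)
        first = denoise.denoise_sequence(frames_from_raw(raws))
        # re-embed the cleaned skeletons as fully-detected raw frames
        raws2 = []
        for s in first:
            j = np.zeros((18, 3))
            j[[1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13], :2] = s.joints * 368
            j[[1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13], 2] = 1.0
            raws2.append(RawSkeleton(j))
        second = denoise.denoise_sequence(frames_from_raw(raws2))
        assert len(second) == len(first)
        for a, b in zip(first, second):
            np.testing.assert_allclose(b.joints, a.joints, atol=1e-12)

    def test_static_relative_joint_imputed_exactly(self):
        # a wrist rigidly attached to the neck is recovered exactly when missing
        base = full_raw(np.random.default_rng(8))
        raws = []
        for t in range(6):
            j = base.joints.copy()
            j[:, 0] += 3.0 * t  # whole body translates
            if t in (2, 3):
                j[4] = 0.0  # RWrist missing
            raws.append(RawSkeleton(j))
        out = denoise.denoise_sequence(frames_from_raw(raws))
        expected_offset = (base.joints[4, :2] - base.joints[1, :2]) / 368
        for s in out:
            np.testing.assert_allclose(s.joints[3] - s.joints[0], expected_offset,
                                       atol=1e-12)

    def test_all_invalid_gives_empty_with_warning(self, caplog):
        raws = [RawSkeleton(np.zeros((18, 3))) for _ in range(3)]
        import logging
        with caplog.at_level(logging.WARNING):
            out = denoise.denoise_sequence(frames_from_raw(raws))
        assert out == []
        assert any("invalid" in r.message for r in caplog.records)
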