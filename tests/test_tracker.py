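import numpy as np
import pytest

from stereokit import tracker
from stereokit.synthetic import NO_NOISE, generate_multiperson_scene, make_templates
from stereokit.types import CleanSkeleton

from conftest import random_clean_skeleton

IMG = (656, 368)


def skel_at(x, y, frame_index=0, valid=None):
    joints = np.tile([x, y], (13, 1)) + np.linspace(0, 0.1, 26).reshape(13, 2)
    v = np.ones(13, dtype=bool) if valid is None else np.asarray(valid)
    return CleanSkeleton(joints=joints, valid=v, frame_index=frame_index)


class TestCenterDistance:
    def test_neck_at_center_is_zero(self):
        s = skel_at(0, 0)
        s.joints[0] = tracker.image_center(IMG)
        assert tracker.center_distance(s, IMG) == 0.0

    def test_pythagoras(self):
        s = skel_at(0, 0)
        s.joints[0] = tracker.image_center(IMG) + [0.3, 0.4]
        assert tracker.center_distance(s, IMG) == pytest.approx(0.5)

    def test_invariant_to_other_joints(self):
        rng = np.random.default_rng(0)
        s1 = random_clean_skeleton(rng)
        s2 = CleanSkeleton(s1.joints.copy(), s1.valid.copy())
        s2.joints[1:] = rng.uniform(0, 1, (12, 2))
        assert tracker.center_distance(s1, IMG) == tracker.center_distance(s2, IMG)


class TestSortByCenter:
    def test_central_first(self):
        cx, cy = tracker.image_center(IMG)
        outer, central = skel_at(0.1, 0.1), skel_at(0, 0)
        central.joints[0] = (cx, cy)
        assert tracker.sort_by_center([outer, central], IMG)[0] is central

    def test_stable_on_ties(self):
        a, b = skel_at(0.2, 0.3), skel_at(0.5, 0.5)
        b.joints[0] = a.joints[0]
        assert tracker.sort_by_center([a, b], IMG) == [a, b]

    def test_empty(self):
        assert tracker.sort_by_center([], IMG) == []


class TestSkeletonDistance:
    def test_identical_is_zero(self):
        s = skel_at(0.5, 0.5)
        assert tracker.skeleton_distance(s, s) == 0.0

    def test_translation(self):
        a = skel_at(0.4, 0.5)
        b = CleanSkeleton(a.joints + [0.07, 0.0], a.valid.copy())
        assert tracker.skeleton_distance(a, b) == pytest.approx(0.07)

    def test_only_necks_shared_reduces_to_neck_distance(self):
        a = skel_at(0.4, 0.5, valid=[True] + [False] * 12)
        b = skel_at(0.6, 0.5)
        d = tracker.skeleton_distance(a, b)
        assert d == pytest.approx(np.linalg.norm(a.joints[0] - b.joints[0]))

    def test_no_shared_joints_is_inf(self):
        a = skel_at(0.4, 0.5, valid=[True] + [False] * 12)
        b = skel_at(0.4, 0.5, valid=[False, True] + [False] * 11)
        assert tracker.skeleton_distance(a, b) == float("inf")

    def test_matches_bruteforce_mean_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = random_clean_skeleton(rng, n_valid=int(rng.integers(1, 14)))
            b = random_clean_skeleton(rng, n_valid=int(rng.integers(1, 14)))
            shared = [j for j in range(13) if a.valid[j] and b.valid[j]]
            if shared:
                expect = sum(
                    float(np.hypot(*(a.joints[j] - b.joints[j]))) for j in shared
                ) / len(shared)
            else:
                expect = float("inf")
            assert tracker.skeleton_distance(a, b) == pytest.approx(expect)


def oracle_mutual_pairs(dist, threshold):
    """Exhaustive enumeration of the mutual-nearest rule (pure python)."""
    n, m = len(dist), len(dist[0])
    pairs = []
    for i in range(n):
        for j in range(m):
            d = dist[i][j]
            if not (d < threshold):
                continue
            if any(dist[i][jj] < d or (dist[i][jj] == d and jj < j) for jj in range(m) if jj != j):
                continue
            if any(dist[ii][j] < d or (dist[ii][j] == d and ii < i) for ii in range(n) if ii != i):
                continue
            pairs.append((i, j))
    return pairs


class TestMatchFrames:
    def _tracked(self, skeletons, start_id=0):
        return [tracker.TrackedSkeleton(start_id + k, s, s.frame_index)
                for k, s in enumerate(skeletons)]

    def test_single_person_small_motion_keeps_id(self):
        state = tracker.TrackerState(next_id=5)
        prev = self._tracked([skel_at(0.8, 0.5)], start_id=3)
        curr = [skel_at(0.82, 0.5, frame_index=1)]
        out = tracker.match_frames(prev, curr, state)
        assert out[0].person_id == 3

    def test_exit_and_far_entry_gets_new_id(self):
        state = tracker.TrackerState(next_id=2)
        prev = self._tracked([skel_at(0.3, 0.5)])
        curr = [skel_at(1.4, 0.5, frame_index=1)]  # far beyond threshold
        out = tracker.match_frames(prev, curr, state)
        assert out[0].person_id == 2  # fresh id; id 0 retired

    def test_mutual_nearest_equals_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        state_threshold = 0.25
        for _ in range(200):
            n, m = rng.integers(1, 5), rng.integers(1, 5)
            prev_s = [random_clean_skeleton(rng) for _ in range(n)]
            curr_s = [random_clean_skeleton(rng, frame_index=1) for _ in range(m)]
            dist = [[tracker.skeleton_distance(a, b) for b in curr_s] for a in prev_s]
            got = tracker.mutual_nearest_pairs(np.asarray(dist), state_threshold)
            assert sorted(got) == sorted(oracle_mutual_pairs(dist, state_threshold))

    def test_pairing_symmetric_under_transpose(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = rng.uniform(0, 0.5, (int(rng.integers(1, 5)), int(rng.integers(1, 5))))
            fwd = tracker.mutual_nearest_pairs(d, 0.25)
            rev = tracker.mutual_nearest_pairs(d.T, 0.25)
            assert sorted(fwd) == sorted((j, i) for i, j in rev)

    def test_matched_set_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            d = rng.uniform(0, 0.5, (3, 3))
            small = set(tracker.mutual_nearest_pairs(d, 0.1))
            large = set(tracker.mutual_nearest_pairs(d, 0.4))
            assert small <= large

    def test_no_duplicate_ids_within_frame(self):
        rng = np.random.default_rng(5)
        state = tracker.TrackerState(next_id=4)
        prev = self._tracked([random_clean_skeleton(rng) for _ in range(4)])
        curr = [random_clean_skeleton(rng, frame_index=1) for _ in range(4)]
        out = tracker.match_frames(prev, curr, state)
        ids = [t.person_id for t in out]
        assert len(ids) == len(set(ids))


class TestInitIds:
    def test_central_person_gets_id_zero(self):
        cx, cy = tracker.image_center(IMG)
        outer, central = skel_at(0.1, 0.1), skel_at(0, 0)
        central.joints[0] = (cx, cy)
        state = tracker.TrackerState()
        out = tracker.init_ids([outer, central], IMG, state)
        assert out[0].skeleton is central and out[0].person_id == 0

    def test_ids_are_bijection(self):
        rng = np.random.default_rng(6)
        skels = [random_clean_skeleton(rng) for _ in range(5)]
        out = tracker.init_ids(skels, IMG, tracker.TrackerState())
        assert sorted(t.person_id for t in out) == [0, 1, 2, 3, 4]


class TestTrack:
    def test_two_separated_walkers_no_id_switches(self):
        frames, true_ids, _ = generate_multiperson_scene(
            2, n_frames=100, noise=NO_NOISE, seed=7)
        from stereokit.pipeline import frames_to_clean
        clean = frames_to_clean(frames)
        tracks = tracker.track(clean, IMG)
        assert len(tracks) == 2
        assert all(len(seq) == 100 for seq in tracks.values())
        # person identity is consistent: each track's neck stays near one
        # ground-truth person throughout
        for seq in tracks.values():
            necks = np.array([s.joints[0] for s in seq.skeletons])
            assert np.abs(np.diff(necks, axis=0)).max() < 0.05

    def test_gap_frame_preserves_ids(self):
        a = [skel_at(0.5, 0.4, t) for t in range(3)]
        b = [skel_at(1.2, 0.6, t) for t in range(3)]
        frames = [[a[0], b[0]], [], [a[2], b[2]]]
        tracks = tracker.track(frames, IMG)
        assert len(tracks) == 2
        assert all(seq.frame_indices == [0, 2] for seq in tracks.values())

    def test_crossing_outside_threshold_no_switch(self):
        # two people approach but never get closer than threshold + motion
        left = [skel_at(0.4 + 0.003 * t, 0.5, t) for t in range(40)]
        right = [skel_at(1.3 - 0.003 * t, 0.5, t) for t in range(40)]
        tracks = tracker.track([[l, r] for l, r in zip(left, right)], IMG,
                               threshold=0.1)
        assert len(tracks) == 2
        for seq in tracks.values():
            xs = np.array([s.joints[0, 0] for s in seq.skeletons])
            # each track is monotone in x: no identity swap happened
            diffs = np.diff(xs)
            assert (diffs > 0).all() or (diffs < 0).all()
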