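"""Multi-person tracking by mutual-nearest skeleton matching.

Appearance-free tracking for a fixed camera: each person in a new frame is
matched to a person in the previous frame when the two skeletons are each
other's unique nearest neighbours under a mean per-joint distance and that
distance is below a preset threshold.  Unmatched skeletons in the current
frame are new people and receive fresh ids; ids are never reused.

Skeletons within a frame are processed in ascending order of the distance
between their Neck and the image centre, which also defines the id order on
the first frame (the most central person gets id 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import CleanSkeleton, NECK, TrackedSequence

#: Default match threshold in scaled units (fraction of image height).
DEFAULT_THRESHOLD = 0.25


@dataclass
class TrackedSkeleton:
    person_id: int
    skeleton: CleanSkeleton
    frame_index: int


@dataclass
class TrackerState:
    last_frame: list[TrackedSkeleton] = field(default_factory=list)
    next_id: int = 0
    match_threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.match_threshold <= 0:
            raise ValueError("match threshold must be positive")


def image_center(image_size: tuple[int, int]) -> np.ndarray:
    """Image centre in scaled coordinates: (w/2h, 1/2)."""
    w, h = image_size
    return np.array([w / (2 * h), 0.5])


def center_distance(s: CleanSkeleton, image_size: tuple[int, int]) -> float:
    """Euclidean distance from the Neck to the image centre, scaled units."""
    return float(np.linalg.norm(s.joints[NECK] - image_center(image_size)))


def sort_by_center(
    skeletons: list[CleanSkeleton], image_size: tuple[int, int]
) -> list[CleanSkeleton]:
    """Stable ascending sort by Neck-to-centre distance."""
    return sorted(skeletons, key=lambda s: center_distance(s, image_size))


def skeleton_distance(a: CleanSkeleton, b: CleanSkeleton) -> float:
    """Mean Euclidean distance over joints valid in both skeletons.

    Reduces to the Neck-to-Neck distance when only the Necks are shared;
    +inf when no joint is shared (the pair can never match).
    """
    shared = a.valid & b.valid
    if not shared.any():
        return float("inf")
    d = np.linalg.norm(a.joints[shared] - b.joints[shared], axis=1)
    return float(d.mean())


def init_ids(
    skeletons: list[CleanSkeleton],
    image_size: tuple[int, int],
    state: TrackerState,
) -> list[TrackedSkeleton]:
    """Assign ids 0, 1, ... in ascending centre-distance order on the first frame."""
    if state.last_frame or state.next_id != 0:
        raise ValueError("init_ids requires an empty tracker state")
    tracked = []
    for s in sort_by_center(skeletons, image_size):
        tracked.append(TrackedSkeleton(state.next_id, s, s.frame_index))
        state.next_id += 1
    state.last_frame = tracked
    return tracked


def mutual_nearest_pairs(
    dist: np.ndarray, threshold: float
) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour pairs (i, j) of a distance matrix under a threshold.

    A pair matches iff row i's unique minimum is column j, column j's unique
    minimum is row i, and ``dist[i, j] < threshold``.  Ties in a row or
    column minimum are broken toward the lower index, which makes the result
    deterministic for centre-sorted input.
    """
    if dist.size == 0:
        return []
    pairs = []
    for i in range(dist.shape[0]):
        j = int(np.argmin(dist[i]))  # argmin takes the lowest index on ties
        if np.isfinite(dist[i, j]) and dist[i, j] < threshold and int(np.argmin(dist[:, j])) == i:
            pairs.append((i, j))
    return pairs


def match_frames(
    prev: list[TrackedSkeleton],
    curr: list[CleanSkeleton],
    state: TrackerState,
) -> list[TrackedSkeleton]:
    """Match current skeletons to the previous frame and assign ids.

    ``curr`` should be centre-sorted.  Matched skeletons inherit the
    previous person's id; unmatched current skeletons are new people and get
    fresh ids.  Previous people with no match simply have no entry in this
    frame (their id is retired unless re-matched while still in
    ``state.last_frame``).
    """
    dist = np.array(
        [[skeleton_distance(p.skeleton, c) for c in curr] for p in prev]
    ).reshape(len(prev), len(curr))
    matched_j: dict[int, int] = {
        j: prev[i].person_id
        for i, j in mutual_nearest_pairs(dist, state.match_threshold)
    }
    tracked = []
    for j, c in enumerate(curr):
        if j in matched_j:
            pid = matched_j[j]
        else:
            pid = state.next_id
            state.next_id += 1
        tracked.append(TrackedSkeleton(pid, c, c.frame_index))
    state.last_frame = tracked
    return tracked


def track(
    frames: list[list[CleanSkeleton]],
    image_size: tuple[int, int],
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[int, TrackedSequence]:
    """Track people across a time-ordered sequence of per-frame skeleton lists.

    Empty frames are skipped; the previous reference frame is the last frame
    that contained any skeleton, so a single detection failure does not
    orphan every id (re-matching across the gap still has to pass the
    threshold).  Returns one time-ordered sequence per person id.
    """
    state = TrackerState(match_threshold=threshold)
    sequences: dict[int, TrackedSequence] = {}
    initialized = False
    for skeletons in frames:
        if not skeletons:
            continue
        ordered = sort_by_center(skeletons, image_size)
        if not initialized:
            tracked = init_ids(ordered, image_size, state)
            initialized = True
        else:
            tracked = match_frames(state.last_frame, ordered, state)
        for t in tracked:
            seq = sequences.setdefault(t.person_id, TrackedSequence(t.person_id))
            seq.skeletons.append(t.skeleton)
    return sequences
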