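"""Turning tracked skeleton streams into fixed-length classifier inputs.

The classifier consumes windows of exactly T frames of 13 x/y joint pairs.
Clips shorter than T are padded with all-zero skeleton frames at the end;
clips longer than T are shortened by sampling T distinct frames uniformly
at random, keeping the original order.  Multi-person frames are reduced to
the single person closest to the image centre before denoising, and train /
test splits are stratified per class at the sequence level so no window of
one clip ever appears on both sides.
"""

from __future__ import annotations

import numpy as np

from .tracker import center_distance
from .types import ActionSample, CleanSkeleton, FrameDetections, RawSkeleton, TrackedSequence

#: Best window length found in the hyperparameter sweep (~1.3 s at 25 fps).
DEFAULT_TIME_STEPS = 32


def normalize_length(
    seq: list[CleanSkeleton] | np.ndarray,
    T: int,
    rng: np.random.Generator | None = None,
    label: int | None = None,
    source: tuple[str, int] | None = None,
) -> ActionSample:
    """Pad (with trailing all-zero frames) or subsample a clip to exactly T frames.

    Subsampling draws T distinct frame positions uniformly at random and
    keeps them in their original order; ``rng`` makes it reproducible.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    arr = seq if isinstance(seq, np.ndarray) else (
        np.stack([s.joints for s in seq]) if seq else np.empty((0, 13, 2))
    )
    n = arr.shape[0]
    if n == 0:
        raise ValueError("cannot normalize an empty sequence")
    if n < T:
        pad = np.zeros((T - n, 13, 2))
        data = np.concatenate([arr, pad], axis=0)
    elif n > T:
        if rng is None:
            rng = np.random.default_rng()
        keep = np.sort(rng.choice(n, size=T, replace=False))
        data = arr[keep]
    else:
        data = arr.copy()
    return ActionSample(data=data, label=label, source=source)


def select_center_person(frames: list[FrameDetections]) -> list[FrameDetections]:
    """Keep only the skeleton nearest the image centre in each frame.

    Distance is the Neck-to-centre distance in scaled units; a skeleton with
    no Neck sorts last.  Ties keep the lowest original index.  Frames with
    no people pass through unchanged.
    """
    from .denoise import remove_head_joints, scale_coordinates
    from .types import NECK

    out = []
    for fr in frames:
        if len(fr.skeletons) <= 1:
            out.append(fr)
            continue
        best_i, best_d = 0, np.inf
        for i, s in enumerate(fr.skeletons):
            body13 = remove_head_joints(scale_coordinates(s, fr.image_size))
            if body13[NECK, 2] <= 0:
                continue
            clean = CleanSkeleton(body13[:, :2], body13[:, 2] > 0, fr.frame_index)
            d = center_distance(clean, fr.image_size)
            if d < best_d:
                best_i, best_d = i, d
        out.append(
            FrameDetections(fr.frame_index, fr.image_size, [fr.skeletons[best_i]])
        )
    return out


def sliding_windows(
    seq: TrackedSequence,
    T: int,
    stride: int = 1,
    rng: np.random.Generator | None = None,
) -> list[ActionSample]:
    """Overlapping windows of length T at the given stride.

    The window count is ``ceil(max(len - T, 0) / stride) + 1``; a trailing
    partial window is zero-padded via :func:`normalize_length`.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    arr = seq.as_array()
    n = arr.shape[0]
    if n == 0:
        return []
    starts = list(range(0, max(n - T, 0) + 1, stride))
    if starts[-1] + T < n:  # leftover tail not covered by a full window
        starts.append(starts[-1] + stride)
    return [
        normalize_length(arr[s: s + T], T, rng=rng,
                         source=(str(seq.person_id), s))
        for s in starts
    ]


def train_test_split(
    entries: list[dict],
    fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[dict], list[dict]]:
    """Per-class stratified split of a sequence manifest.

    ``round(n_class * fraction)`` sequences of each class go to the train
    side.  Deterministic under ``seed``; classes with fewer than 2 sequences
    cannot be split and raise.
    """
    if not entries:
        raise ValueError("empty manifest")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[dict]] = {}
    for e in entries:
        by_class.setdefault(e["action_label"], []).append(e)
    train, test = [], []
    for label in sorted(by_class):
        group = by_class[label]
        if len(group) < 2:
            raise ValueError(f"class {label!r} has {len(group)} sequence(s); need >= 2")
        order = rng.permutation(len(group))
        n_train = int(round(len(group) * fraction))
        n_train = min(max(n_train, 1), len(group) - 1)
        train.extend(group[i] for i in sorted(order[:n_train]))
        test.extend(group[i] for i in sorted(order[n_train:]))
    return train, test
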