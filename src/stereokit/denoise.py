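"""The four noise-elimination measures applied to raw pose detections.

Raw 2-D keypoints from a pose estimator are noisy in specific ways: joints
vanish under occlusion, whole detections fail, and pixel coordinates are not
comparable across image aspect ratios.  Four measures address this, applied
in order:

1. **Unit scaling** — divide both coordinate axes by the image height so a
   physical distance maps to the same numeric distance on either axis.
2. **Head-joint removal** — drop Nose, both eyes and both ears; the head's
   position carries almost no action information.  The Neck becomes joint 0
   of the remaining 13.
3. **Invalid-frame discard** — a frame whose skeleton lacks a Neck or both
   hips has lost its torso anchor and is dropped; frames missing only other
   joints are retained.
4. **Neck-relative imputation** — a missing joint is placed at the current
   Neck plus its offset from the Neck in the previous retained frame:
   ``x_i = x_neck + (x_i_prev - x_neck_prev)`` (and likewise for y), so a
   limb that is static relative to the torso is recovered exactly.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    BODY13_COCO_INDICES,
    CleanSkeleton,
    FrameDetections,
    L_HIP,
    NECK,
    R_HIP,
    RawSkeleton,
)

logger = logging.getLogger(__name__)


def scale_coordinates(s: RawSkeleton, image_size: tuple[int, int]) -> RawSkeleton:
    """Divide x and y of every detected joint by the image height.

    Undetected joints (confidence 0) keep their ``(0, 0, 0)`` encoding.
    """
    w, h = image_size
    if h <= 0:
        raise ValueError(f"image height must be positive, got {h}")
    joints = s.joints.copy()
    det = s.detected
    joints[det, 0] /= h
    joints[det, 1] /= h
    return RawSkeleton(joints)


def remove_head_joints(s: RawSkeleton) -> np.ndarray:
    """Drop the five head keypoints, returning a (13, 3) array with Neck at row 0."""
    if s.joints.shape[0] != 18:
        raise ValueError(f"expected 18 joints, got {s.joints.shape[0]}")
    return s.joints[list(BODY13_COCO_INDICES)].copy()


def is_valid_frame(body13: np.ndarray, min_confidence: float = 0.0) -> bool:
    """A frame is valid iff the Neck and at least one hip are detected.

    ``body13`` is a (13, 3) array as produced by :func:`remove_head_joints`.
    """
    c = body13[:, 2]
    return bool(c[NECK] > min_confidence and
                (c[R_HIP] > min_confidence or c[L_HIP] > min_confidence))


def fill_missing_joints(
    frames: list[np.ndarray],
    frame_indices: list[int] | None = None,
    min_confidence: float = 0.0,
) -> list[CleanSkeleton]:
    """Impute missing joints from their Neck-relative position in the previous frame.

    Every input frame must already be valid (Neck present).  A joint missing
    in frame t is placed at ``neck_t + (joint_{t-1} - neck_{t-1})``, where
    the previous value may itself be imputed, so a joint missing for k
    consecutive frames keeps a constant Neck offset.  A joint never yet
    observed is placed at the Neck (zero offset).  Imputed joints are
    flagged ``valid = False``; observed joints are never altered.
    """
    if not frames:
        raise ValueError("cannot impute an empty sequence")
    if frame_indices is None:
        frame_indices = list(range(len(frames)))
    out: list[CleanSkeleton] = []
    prev: np.ndarray | None = None  # previous (13, 2) dense coordinates
    for body13, fi in zip(frames, frame_indices):
        detected = body13[:, 2] > min_confidence
        if not detected[NECK]:
            raise ValueError(f"frame {fi}: Neck missing; filter invalid frames first")
        coords = body13[:, :2].copy()
        neck = coords[NECK]
        missing = ~detected
        if prev is None:
            coords[missing] = neck  # no history: zero offset from the Neck
        else:
            offsets = prev - prev[NECK]
            coords[missing] = neck + offsets[missing]
        out.append(CleanSkeleton(joints=coords, valid=detected.copy(), frame_index=fi))
        prev = coords
    return out


def select_skeleton(frame: FrameDetections, person_index: int = 0) -> RawSkeleton | None:
    if person_index < len(frame.skeletons):
        return frame.skeletons[person_index]
    return None


def denoise_sequence(
    frames: list[FrameDetections],
    min_confidence: float = 0.0,
) -> list[CleanSkeleton]:
    """Apply all four measures to a single-person frame sequence.

    Multi-person frames must be reduced to one skeleton per frame first
    (see :func:`stereokit.sequence_prep.select_center_person`); here the
    first skeleton of each frame is used and empty frames are dropped as
    invalid.  Output frames keep their original frame indices.
    """
    kept: list[np.ndarray] = []
    kept_idx: list[int] = []
    for fr in frames:
        s = select_skeleton(fr)
        if s is None:
            continue  # whole-frame detection failure
        scaled = scale_coordinates(s, fr.image_size)
        body13 = remove_head_joints(scaled)
        if is_valid_frame(body13, min_confidence):
            kept.append(body13)
            kept_idx.append(fr.frame_index)
    if not kept:
        logger.warning("denoise: all %d frames invalid, empty result", len(frames))
        return []
    return fill_missing_joints(kept, kept_idx, min_confidence)
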