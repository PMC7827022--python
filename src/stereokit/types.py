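"""Core data containers shared by every pipeline stage.

Coordinate conventions
----------------------
Raw keypoints are pixel coordinates in an image of size ``(w, h)`` with the
y axis growing downward, exactly as a 2-D pose estimator emits them.  An
undetected joint is the triple ``(0, 0, 0)`` (x, y, confidence).  After unit
scaling both axes are divided by the image height ``h``, so scaled y lies in
``[0, 1]`` and scaled x in ``[0, w/h]``; Euclidean distances are then
isotropic, which the tracker and the velocity features rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: COCO 18-keypoint body layout, in emission order.
COCO18_NAMES = (
    "Nose", "Neck",
    "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist",
    "RHip", "RKnee", "RAnkle",
    "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar",
)

#: Indices of the five head keypoints that carry no action information.
HEAD_JOINTS = (0, 14, 15, 16, 17)

#: COCO-18 indices retained after head removal, Neck first.
BODY13_COCO_INDICES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13)

#: Names of the 13 body joints in their post-removal order (joint 0 = Neck).
BODY13_NAMES = tuple(COCO18_NAMES[i] for i in BODY13_COCO_INDICES)

NECK = 0
R_HIP = BODY13_NAMES.index("RHip")
L_HIP = BODY13_NAMES.index("LHip")
R_WRIST = BODY13_NAMES.index("RWrist")
L_WRIST = BODY13_NAMES.index("LWrist")
R_ANKLE = BODY13_NAMES.index("RAnkle")
L_ANKLE = BODY13_NAMES.index("LAnkle")

#: The five stereotyped-action classes, in label-index order.
ACTIONS = ("sit", "stand", "squat", "shake_body", "shake_hands")
N_CLASSES = len(ACTIONS)
ACTION_INDEX = {name: i for i, name in enumerate(ACTIONS)}


@dataclass
class RawSkeleton:
    """One person's 18-keypoint detection in one frame.

    ``joints`` is an (18, 3) float array of (x, y, confidence) rows in COCO
    order.  A joint with confidence 0 is undetected and its coordinates are
    meaningless (stored as 0).
    """

    joints: np.ndarray

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.shape != (18, 3):
            raise ValueError(
                f"RawSkeleton requires an (18, 3) joint array, got {self.joints.shape}"
            )

    @property
    def detected(self) -> np.ndarray:
        """Boolean mask of joints with positive confidence."""
        return self.joints[:, 2] > 0


@dataclass
class FrameDetections:
    """All skeleton detections of a single video frame."""

    frame_index: int
    image_size: tuple[int, int]  # (w, h) in pixels
    skeletons: list[RawSkeleton] = field(default_factory=list)

    def __post_init__(self) -> None:
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError(f"image size must be positive, got {self.image_size}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


@dataclass
class CleanSkeleton:
    """A denoised 13-joint skeleton in unit-scaled coordinates.

    ``joints`` is a (13, 2) array with the Neck at row 0.  ``valid[i]`` is
    True when joint i was observed by the detector and False when it was
    imputed (or is absent pre-imputation).
    """

    joints: np.ndarray
    valid: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.joints.shape != (13, 2):
            raise ValueError(
                f"CleanSkeleton requires a (13, 2) joint array, got {self.joints.shape}"
            )
        if self.valid.shape != (13,):
            raise ValueError("valid must be a 13-element boolean vector")


@dataclass
class TrackedSequence:
    """Time-ordered clean skeletons attributed to one person id."""

    person_id: int
    skeletons: list[CleanSkeleton] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.skeletons)

    @property
    def frame_indices(self) -> list[int]:
        return [s.frame_index for s in self.skeletons]

    def as_array(self) -> np.ndarray:
        """Stack into an (n_frames, 13, 2) coordinate array."""
        return np.stack([s.joints for s in self.skeletons])


@dataclass
class ActionSample:
    """Fixed-length classifier input: a (T, 13, 2) window plus optional label."""

    data: np.ndarray
    label: int | None = None
    source: tuple[str, int] | None = None  # (sequence id, start frame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1:] != (13, 2):
            raise ValueError(
                f"ActionSample requires a (T, 13, 2) array, got {self.data.shape}"
            )

    @property
    def time_steps(self) -> int:
        return self.data.shape[0]
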