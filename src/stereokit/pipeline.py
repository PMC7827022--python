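"""End-to-end wiring: denoise -> track -> window + classify.

For multi-person input the four denoising measures split around the
tracker: unit scaling, head removal and invalid-frame discard are per-frame
operations and run first, while the neck-relative imputation needs each
person's *own* previous frame and therefore runs on every tracked sequence
after id assignment.  The single-person path in
:func:`stereokit.denoise.denoise_sequence` applies all four in one pass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .classifier import ActionRecognitionModel, DETECTION_THRESHOLD
from .denoise import fill_missing_joints, is_valid_frame, remove_head_joints, scale_coordinates
from .sequence_prep import sliding_windows
from .tracker import DEFAULT_THRESHOLD, track
from .types import ACTIONS, CleanSkeleton, FrameDetections, TrackedSequence

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for the full recognition pipeline."""

    time_steps: int = 32
    hidden_states: int = 128
    learning_rate: float = 0.001
    match_threshold: float = DEFAULT_THRESHOLD
    detection_threshold: float = DETECTION_THRESHOLD
    window_stride: int = 16
    min_confidence: float = 0.0
    seed: int = 0
    noise: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_steps < 1 or self.hidden_states < 1:
            raise ValueError("time_steps and hidden_states must be >= 1")
        if self.match_threshold <= 0:
            raise ValueError("match_threshold must be positive")
        if not 0 <= self.min_confidence < 1:
            raise ValueError("min_confidence must be in [0, 1)")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls(**payload)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def frames_to_clean(
    frames: list[FrameDetections], min_confidence: float = 0.0
) -> list[list[CleanSkeleton]]:
    """Scale, strip head joints and drop invalid skeletons, per frame.

    Joints not yet observed keep coordinate (0, 0) with valid=False; the
    imputation step fills them once the person is tracked.
    """
    out: list[list[CleanSkeleton]] = []
    for fr in frames:
        kept = []
        for s in fr.skeletons:
            body13 = remove_head_joints(scale_coordinates(s, fr.image_size))
            if not is_valid_frame(body13, min_confidence):
                continue
            valid = body13[:, 2] > min_confidence
            coords = np.where(valid[:, None], body13[:, :2], 0.0)
            kept.append(CleanSkeleton(coords, valid, fr.frame_index))
        out.append(kept)
    return out


def impute_tracked(seq: TrackedSequence) -> TrackedSequence:
    """Apply the neck-relative missing-joint fill to one person's track."""
    body = [np.column_stack([s.joints, s.valid.astype(float)]) for s in seq.skeletons]
    filled = fill_missing_joints(body, frame_indices=seq.frame_indices)
    return TrackedSequence(person_id=seq.person_id, skeletons=filled)


def run_pipeline(
    frames: list[FrameDetections],
    model: ActionRecognitionModel,
    config: PipelineConfig,
) -> list[dict]:
    """Per-person action detections from raw multi-person keypoint frames.

    Returns one record per window whose winning probability strictly
    exceeds the detection threshold:
    ``{"person_id", "start_frame", "end_frame", "label", "probability"}``.
    """
    if not frames:
        logger.warning("run_pipeline: empty input, empty report")
        return []
    image_size = frames[0].image_size
    clean = frames_to_clean(frames, config.min_confidence)
    tracks = track(clean, image_size, threshold=config.match_threshold)
    rng = np.random.default_rng(config.seed)
    report = []
    for pid in sorted(tracks):
        seq = impute_tracked(tracks[pid])
        if len(seq) == 0:
            continue
        indices = seq.frame_indices
        for w in sliding_windows(seq, config.time_steps, config.window_stride, rng=rng):
            start = int(w.source[1])
            end = min(start + config.time_steps, len(indices)) - 1
            pred = model.predict(w, threshold=config.detection_threshold)
            if pred.detected is None:
                continue
            report.append({
                "person_id": pid,
                "start_frame": indices[start],
                "end_frame": indices[end],
                "label": ACTIONS[pred.detected],
                "probability": float(pred.probs[pred.detected]),
            })
    return report
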