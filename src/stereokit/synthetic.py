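"""Seeded generator of labeled multi-person skeleton sequences.

The study data this emulates are short indoor video clips (1-3 s at 25 fps,
image size 656 x 368) of children performing one of five actions: sit,
stand (sit-to-stand transition), squat (stand-to-crouch), shake_body
(rocking the torso while seated) and shake_hands (oscillating the hands).
The clips pass through a 2-D pose estimator, whose output is noisy: joints
drop out under occlusion, whole frames fail, coordinates jitter.

Each action class is a :class:`MotionTemplate`: a start pose, a smooth
postural ramp (for the transitions), and per-joint sinusoidal terms (for
the stereotyped oscillations).  shake_body deliberately shares its seated
base pose with sit, so the two classes are confusable except for the torso
oscillation — mirroring the hardest confusion in real data.  The generator
returns both the noise-free ground truth and the corrupted detector-style
output, so denoising error is directly measurable.  All randomness flows
from one seed; identical seeds give identical datasets.

Templates are stylized kinematics, not biomechanical models: what they
guarantee is class-conditional separation (e.g. mean wrist speed of
shake_hands exceeds sit's by a wide margin), not anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    ACTIONS,
    ACTION_INDEX,
    BODY13_COCO_INDICES,
    CleanSkeleton,
    FrameDetections,
    HEAD_JOINTS,
    NECK,
    RawSkeleton,
)

FPS = 25
IMAGE_SIZE = (656, 368)
DURATION_RANGE = (25, 75)  # 1-3 s at 25 fps

# ---------------------------------------------------------------------------
# Stick-figure poses, scaled units (y grows downward), origin at the mid-hip
# of the standing pose.

_STANDING = np.array([
    (0.00, -0.28),             # Neck
    (-0.08, -0.26), (-0.12, -0.16), (-0.13, -0.05),   # R shoulder/elbow/wrist
    (0.08, -0.26), (0.12, -0.16), (0.13, -0.05),      # L shoulder/elbow/wrist
    (-0.05, 0.00), (-0.05, 0.14), (-0.05, 0.28),      # R hip/knee/ankle
    (0.05, 0.00), (0.05, 0.14), (0.05, 0.28),         # L hip/knee/ankle
])

# Seated: hips dropped, thighs near horizontal, shins tucked.
_SEATED = np.array([
    (0.00, -0.12),
    (-0.08, -0.10), (-0.12, 0.00), (-0.13, 0.10),
    (0.08, -0.10), (0.12, 0.00), (0.13, 0.10),
    (-0.05, 0.14), (-0.12, 0.16), (-0.12, 0.28),
    (0.05, 0.14), (0.12, 0.16), (0.12, 0.28),
])

# Deep crouch: hips almost at knee height.
_CROUCH = np.array([
    (0.00, -0.06),
    (-0.08, -0.04), (-0.12, 0.04), (-0.13, 0.12),
    (0.08, -0.04), (0.12, 0.04), (0.13, 0.12),
    (-0.06, 0.16), (-0.13, 0.18), (-0.10, 0.28),
    (0.06, 0.16), (0.13, 0.18), (0.10, 0.28),
])

_TORSO = (0, 1, 2, 3, 4, 5, 6)      # neck, shoulders, elbows, wrists
_ARMS = (2, 3, 5, 6)                # elbows + wrists
_WRISTS = (3, 6)

#: Oscillation amplitude (scaled units) of the torso in shake_body and the
#: wrists in shake_hands — the separability knob between the shake classes
#: and their static look-alikes.  0.08 scaled units is ~30% of the trunk
#: (Neck-to-hip) length, a typical excursion for seated body rocking.
SHAKE_BODY_AMPLITUDE = 0.08
SHAKE_HANDS_AMPLITUDE = 0.06


@dataclass
class MotionTemplate:
    """Parametric kinematics of one action class.

    Joint position at frame t of an n-frame clip:

        pose(t) = start + ramp * smoothstep(t / (n-1))
                  + amp * sin(2 pi freq * t / fps + phase)

    ``start`` and ``ramp`` are (13, 2) arrays in scaled units; ``amp`` is
    (13, 2); ``freq`` is in Hz and ``phase`` a scalar offset.
    """

    label: str
    start: np.ndarray
    ramp: np.ndarray
    amp: np.ndarray
    freq: float = 0.0
    duration_range: tuple[int, int] = DURATION_RANGE

    def pose_at(self, t: int, n_frames: int, phase: float = 0.0,
                freq_scale: float = 1.0, amp_scale: float = 1.0) -> np.ndarray:
        u = t / max(n_frames - 1, 1)
        ramp_frac = u * u * (3 - 2 * u)  # smoothstep: eases in and out
        wave = np.sin(2 * np.pi * self.freq * freq_scale * t / FPS + phase)
        return self.start + self.ramp * ramp_frac + amp_scale * self.amp * wave


def make_templates() -> dict[str, MotionTemplate]:
    """The five action templates keyed by label."""
    zero = np.zeros((13, 2))

    def amp_for(joints, ax: int, a: float, base=None):
        out = zero.copy() if base is None else base.copy()
        for j in joints:
            out[j, ax] = a
        return out

    sit = MotionTemplate(
        label="sit",
        start=_SEATED.copy(),
        ramp=zero.copy(),
        # barely-visible postural sway so the class is not perfectly static
        amp=amp_for(_TORSO, 0, 0.002),
        freq=0.4,
    )
    stand = MotionTemplate(
        label="stand",
        start=_SEATED + (0.0, 0.12),       # seated low in the frame ...
        ramp=_STANDING - (_SEATED + (0.0, 0.12)),  # ... rising to upright
        amp=zero.copy(),
    )
    squat = MotionTemplate(
        label="squat",
        start=_STANDING.copy(),
        ramp=(_CROUCH + (0.0, 0.10)) - _STANDING,  # sinking into a crouch
        amp=zero.copy(),
    )
    shake_body = MotionTemplate(
        label="shake_body",
        start=_SEATED.copy(),               # same base pose as sit
        ramp=zero.copy(),
        amp=amp_for(_TORSO, 0, SHAKE_BODY_AMPLITUDE,
                    base=amp_for((7, 10), 0, 0.008)),
        freq=1.5,
    )
    shake_hands = MotionTemplate(
        label="shake_hands",
        start=_STANDING.copy(),
        ramp=zero.copy(),
        amp=amp_for(_WRISTS, 1, SHAKE_HANDS_AMPLITUDE,
                    base=amp_for(_ARMS, 0, 0.03)),
        freq=2.5,
    )
    return {t.label: t for t in (sit, stand, squat, shake_body, shake_hands)}


@dataclass
class OcclusionEvent:
    """Joints of one person hidden for a span of frames."""

    person: int
    joints: tuple[int, ...]  # COCO-18 indices
    start: int
    stop: int  # exclusive


@dataclass
class NoiseModel:
    """Detector-noise parameters applied to the ground-truth kinematics."""

    joint_dropout_rate: float = 0.2
    frame_loss_rate: float = 0.05
    jitter_sd: float = 0.005  # scaled units
    occlusions: list[OcclusionEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.joint_dropout_rate <= 1 and 0 <= self.frame_loss_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


NO_NOISE = NoiseModel(joint_dropout_rate=0.0, frame_loss_rate=0.0, jitter_sd=0.0)


@dataclass
class Clip:
    """One generated sequence: corrupted detector output + ground truth."""

    clip_id: str
    label: str
    raw_frames: list[FrameDetections]
    clean: list[CleanSkeleton]

    @property
    def label_index(self) -> int:
        return ACTION_INDEX[self.label]


# ---------------------------------------------------------------------------


def _head_joints_from_neck(neck: np.ndarray) -> np.ndarray:
    """Nose, eyes and ears placed rigidly above the neck, (5, 2)."""
    return neck + np.array([
        (0.0, -0.05),                       # Nose
        (-0.015, -0.06), (0.015, -0.06),    # eyes
        (-0.03, -0.055), (0.03, -0.055),    # ears
    ])


def _to_raw18(body13: np.ndarray, image_size, rng: np.random.Generator,
              jitter_sd: float) -> np.ndarray:
    """Embed a scaled 13-joint pose into an 18-joint pixel skeleton."""
    w, h = image_size
    full = np.zeros((18, 3))
    head = _head_joints_from_neck(body13[NECK])
    scaled = np.empty((18, 2))
    for k, coco in enumerate(BODY13_COCO_INDICES):
        scaled[coco] = body13[k]
    for k, coco in enumerate(HEAD_JOINTS):
        scaled[coco] = head[k]
    if jitter_sd > 0:
        scaled = scaled + rng.normal(0.0, jitter_sd, size=scaled.shape)
    scaled[:, 0] = np.clip(scaled[:, 0], 0.0, w / h)
    scaled[:, 1] = np.clip(scaled[:, 1], 0.0, 1.0)
    full[:, :2] = scaled * h  # back to pixels
    full[:, 2] = rng.uniform(0.5, 1.0, size=18)
    return full


def _clean_pose(body13: np.ndarray, image_size, frame_index: int) -> CleanSkeleton:
    w, h = image_size
    joints = body13.copy()
    joints[:, 0] = np.clip(joints[:, 0], 0.0, w / h)
    joints[:, 1] = np.clip(joints[:, 1], 0.0, 1.0)
    return CleanSkeleton(joints=joints, valid=np.ones(13, dtype=bool),
                         frame_index=frame_index)


def generate_clip(
    template: MotionTemplate,
    duration: int | None = None,
    noise: NoiseModel = NO_NOISE,
    seed: int | np.random.Generator = 0,
    image_size: tuple[int, int] = IMAGE_SIZE,
    center: tuple[float, float] | None = None,
    clip_id: str = "clip",
) -> Clip:
    """Generate one clip: detector-style raw frames plus clean ground truth.

    Per-clip variation (drawn from ``seed``): body scale 0.9-1.1, anchor
    position jitter, oscillation frequency and amplitude within +/-20%, and
    a random phase.  Noise corrupts only the raw frames: per-joint dropout
    writes (0, 0, 0), frame loss empties the frame, jitter perturbs
    coordinates, and occlusion events blank whole joint sets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, h = image_size
    if duration is None:
        duration = int(rng.integers(template.duration_range[0],
                                    template.duration_range[1] + 1))
    if center is None:
        cx = w / (2 * h) + rng.uniform(-0.15, 0.15)
        cy = 0.50 + rng.uniform(-0.05, 0.05)
    else:
        cx, cy = center
    scale = rng.uniform(0.9, 1.1)
    phase = rng.uniform(0, 2 * np.pi)
    freq_scale = rng.uniform(0.8, 1.2)
    amp_scale = rng.uniform(0.8, 1.2)
    mirror = rng.random() < 0.5  # half the clips face the other way

    raw_frames: list[FrameDetections] = []
    clean: list[CleanSkeleton] = []
    occluded = {(ev.person, t, j) for ev in noise.occlusions if ev.person == 0
                for t in range(ev.start, ev.stop) for j in ev.joints}
    for t in range(duration):
        pose = template.pose_at(t, duration, phase=phase,
                                freq_scale=freq_scale, amp_scale=amp_scale)
        pose = pose * scale
        if mirror:
            pose = pose * (-1.0, 1.0)
        pose = pose + (cx, cy)
        clean.append(_clean_pose(pose, image_size, t))
        if rng.random() < noise.frame_loss_rate:
            raw_frames.append(FrameDetections(t, image_size, []))
            continue
        raw = _to_raw18(pose, image_size, rng, noise.jitter_sd)
        drop = rng.random(18) < noise.joint_dropout_rate
        for j in range(18):
            if drop[j] or (0, t, j) in occluded:
                raw[j] = 0.0
        raw_frames.append(FrameDetections(t, image_size, [RawSkeleton(raw)]))
    return Clip(clip_id=clip_id, label=template.label,
                raw_frames=raw_frames, clean=clean)


def generate_dataset(
    n_per_class: int = 150,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    image_size: tuple[int, int] = IMAGE_SIZE,
) -> list[Clip]:
    """A balanced labeled dataset of independent clips, deterministic in seed."""
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    templates = make_templates()
    clips = []
    for label in ACTIONS:
        for k in range(n_per_class):
            clips.append(
                generate_clip(templates[label], noise=noise, seed=rng,
                              image_size=image_size, clip_id=f"{label}_{k:04d}")
            )
    return clips


def export_dataset(clips: list[Clip], out_dir) -> "Path":
    """Write clips as per-frame JSON trees + ground-truth CSVs + a manifest."""
    from pathlib import Path

    from .io import write_manifest, write_openpose_json, write_sequence
    from .types import TrackedSequence

    out_dir = Path(out_dir)
    entries = []
    for clip in clips:
        clip_dir = out_dir / clip.clip_id
        write_openpose_json(clip.raw_frames, clip_dir / "frames")
        truth = TrackedSequence(person_id=0, skeletons=clip.clean)
        write_sequence(truth, clip_dir / "truth.csv")
        entries.append({
            "sequence_path": str(clip_dir.relative_to(out_dir)),
            "action_label": clip.label,
            "n_frames": len(clip.raw_frames),
        })
    manifest = out_dir / "manifest.json"
    write_manifest(entries, manifest)
    return manifest


def generate_multiperson_scene(
    n_people: int,
    n_frames: int = 100,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
    image_size: tuple[int, int] = IMAGE_SIZE,
    templates: list[MotionTemplate] | None = None,
    starts: list[tuple[float, float]] | None = None,
    velocities: list[tuple[float, float]] | None = None,
    min_separation: float = 0.3,
) -> tuple[list[FrameDetections], list[list[int]], list[list[CleanSkeleton]]]:
    """A scene of several people, each following a template plus a drift path.

    Returns ``(frames, true_ids, truth)``: per-frame detections whose
    skeleton order is shuffled, the matching true person index of every
    skeleton, and each person's clean ground-truth track.  Start positions
    closer than ``min_separation`` raise, since overlapping people make the
    ground-truth ids themselves ambiguous.
    """
    if n_people < 1:
        raise ValueError("n_people must be >= 1")
    rng = np.random.default_rng(seed)
    w, h = image_size
    all_templates = list(make_templates().values())
    if templates is None:
        templates = [all_templates[i % len(all_templates)] for i in range(n_people)]
    if starts is None:
        xs = np.linspace(0.35, w / h - 0.35, n_people)
        starts = [(float(x), 0.50) for x in xs]
    for a in range(n_people):
        for b in range(a + 1, n_people):
            d = np.hypot(starts[a][0] - starts[b][0], starts[a][1] - starts[b][1])
            if d < min_separation:
                raise ValueError(
                    f"start positions of people {a} and {b} overlap (d={d:.3f})"
                )
    if velocities is None:
        velocities = [(rng.uniform(-0.002, 0.002), 0.0) for _ in range(n_people)]

    phases = rng.uniform(0, 2 * np.pi, size=n_people)
    occl = {(ev.person, t, j) for ev in noise.occlusions
            for t in range(ev.start, ev.stop) for j in ev.joints}
    frames: list[FrameDetections] = []
    true_ids: list[list[int]] = []
    truth: list[list[CleanSkeleton]] = [[] for _ in range(n_people)]
    for t in range(n_frames):
        skeletons: list[tuple[int, RawSkeleton]] = []
        for p in range(n_people):
            pose = templates[p].pose_at(t % 1000, max(n_frames, 2), phase=phases[p])
            cx = starts[p][0] + velocities[p][0] * t
            cy = starts[p][1] + velocities[p][1] * t
            pose = pose + (cx, cy)
            truth[p].append(_clean_pose(pose, image_size, t))
            raw = _to_raw18(pose, image_size, rng, noise.jitter_sd)
            drop = rng.random(18) < noise.joint_dropout_rate
            for j in range(18):
                if drop[j] or (p, t, j) in occl:
                    raw[j] = 0.0
            if (raw[:, 2] > 0).any():
                skeletons.append((p, RawSkeleton(raw)))
        if rng.random() < noise.frame_loss_rate:
            skeletons = []
        order = rng.permutation(len(skeletons))
        frames.append(FrameDetections(t, image_size,
                                      [skeletons[i][1] for i in order]))
        true_ids.append([skeletons[i][0] for i in order])
    return frames, true_ids, truth
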