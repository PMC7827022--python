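"""Reading and writing the keypoint formats the pipeline touches.

Three formats are supported:

* per-frame pose-estimator JSON (one file per frame, OpenPose dialect:
  ``people[i]["pose_keypoints_2d"]`` as a flat ``x, y, c`` array of 18
  triples, plus ``image_w`` / ``image_h``), with the frame index encoded as
  the last integer in the file name;
* the internal per-person sequence CSV with columns
  ``frame_index, person_id, joint_index, x, y, valid``;
* JSON sequence manifests mapping sequence files to action labels.

Only the COCO-18 keypoint layout is accepted; other array lengths are
rejected so that "missing" semantics stay unambiguous downstream.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ACTIONS, CleanSkeleton, FrameDetections, RawSkeleton, TrackedSequence

logger = logging.getLogger(__name__)

_FRAME_INDEX_RE = re.compile(r"(\d+)(?!.*\d)")


class FormatError(ValueError):
    """Raised when a keypoint file violates the documented layout."""


def _frame_index_from_name(path: Path) -> int:
    m = _FRAME_INDEX_RE.search(path.stem)
    if m is None:
        raise FormatError(f"no frame index found in file name {path.name!r}")
    return int(m.group(1))


def _parse_frame_json(payload: dict, frame_index: int, name: str) -> FrameDetections:
    try:
        w = int(payload["image_w"])
        h = int(payload["image_h"])
    except KeyError as exc:
        raise FormatError(f"{name}: missing image_w/image_h") from exc
    skeletons: list[RawSkeleton] = []
    for i, person in enumerate(payload.get("people", [])):
        kp = person.get("pose_keypoints_2d")
        if kp is None:
            logger.warning("%s: person %d has no pose_keypoints_2d, skipped", name, i)
            continue
        arr = np.asarray(kp, dtype=float)
        if arr.size % 3 != 0:
            raise FormatError(
                f"{name}: person {i} keypoint array length {arr.size} "
                "is not a multiple of 3"
            )
        if arr.size != 54:
            logger.warning(
                "%s: person %d has %d keypoints, expected 18 (COCO); skipped",
                name, i, arr.size // 3,
            )
            continue
        skeletons.append(RawSkeleton(arr.reshape(18, 3)))
    return FrameDetections(frame_index=frame_index, image_size=(w, h), skeletons=skeletons)


def read_openpose_json(path: str | Path) -> list[FrameDetections]:
    """Read a directory of per-frame keypoint JSON files (or one file).

    Frames are ordered by the index embedded in the file name.  Frames with
    an empty ``people`` list are kept, preserving the timeline; malformed
    person entries are skipped with a warning.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.json"), key=_frame_index_from_name)
        if not files:
            raise FileNotFoundError(f"no .json frame files in {path}")
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        files = [path]
    frames = []
    for f in files:
        payload = json.loads(f.read_text())
        frames.append(_parse_frame_json(payload, _frame_index_from_name(f), f.name))
    return frames


def write_openpose_json(frames: list[FrameDetections], out_dir: str | Path) -> list[Path]:
    """Write frames back out in the per-frame JSON dialect read above."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fr in frames:
        payload = {
            "image_w": fr.image_size[0],
            "image_h": fr.image_size[1],
            "people": [
                {"pose_keypoints_2d": [round(v, 6) for v in s.joints.ravel()]}
                for s in fr.skeletons
            ],
        }
        p = out_dir / f"frame_{fr.frame_index:06d}.json"
        p.write_text(json.dumps(payload))
        paths.append(p)
    return paths


SEQUENCE_COLUMNS = ("frame_index", "person_id", "joint_index", "x", "y", "valid")


def write_sequence(seq: TrackedSequence, path: str | Path) -> None:
    """Write one person's skeleton sequence as a tidy CSV (13 rows per frame)."""
    if len(seq) == 0:
        raise ValueError("cannot write an empty sequence")
    rows = []
    for s in seq.skeletons:
        for j in range(13):
            rows.append(
                (s.frame_index, seq.person_id, j,
                 round(float(s.joints[j, 0]), 6), round(float(s.joints[j, 1]), 6),
                 int(s.valid[j]))
            )
    pd.DataFrame(rows, columns=SEQUENCE_COLUMNS).to_csv(path, index=False)


def read_sequence(path: str | Path) -> TrackedSequence:
    """Inverse of :func:`write_sequence` (coordinates to 6 decimal places)."""
    df = pd.read_csv(path)
    missing = set(SEQUENCE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sequence CSV missing columns {sorted(missing)}")
    person_ids = df["person_id"].unique()
    if len(person_ids) != 1:
        raise FormatError(f"{path}: expected a single person id, got {person_ids}")
    skeletons = []
    for frame_index, g in df.groupby("frame_index", sort=True):
        g = g.sort_values("joint_index")
        if list(g["joint_index"]) != list(range(13)):
            raise FormatError(f"{path}: frame {frame_index} does not have joints 0..12")
        skeletons.append(
            CleanSkeleton(
                joints=g[["x", "y"]].to_numpy(),
                valid=g["valid"].to_numpy().astype(bool),
                frame_index=int(frame_index),
            )
        )
    return TrackedSequence(person_id=int(person_ids[0]), skeletons=skeletons)


def write_manifest(entries: list[dict], path: str | Path) -> None:
    """Write a labeled sequence manifest as JSON.

    Each entry is ``{"sequence_path": str, "action_label": str, "n_frames": int}``.
    """
    for e in entries:
        if e["action_label"] not in ACTIONS:
            raise ValueError(f"unknown action label {e['action_label']!r}")
        if e["n_frames"] < 1:
            raise ValueError("n_frames must be >= 1")
    Path(path).write_text(json.dumps({"entries": entries}, indent=1))


def read_manifest(path: str | Path) -> list[dict]:
    payload = json.loads(Path(path).read_text())
    entries = payload["entries"]
    for e in entries:
        if e["action_label"] not in ACTIONS:
            raise FormatError(f"{path}: unknown action label {e['action_label']!r}")
    return entries
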