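"""Reading, validation and gap-filling of per-camera 2D keypoint sequences.

Keypoint streams follow the BODY_25 markerless pose layout: 25 landmarks per
frame, each an ``(u, v, confidence)`` triplet in image pixels.  A confidence
of exactly zero marks a missing detection; its coordinates carry no
information.  Two on-disk dialects are supported:

* one JSON file per frame, ``{"people": [{"pose_keypoints_2d": [u, v, c] * 25}]}``
  (the format emitted by common pose detectors), and
* a consolidated long CSV with columns ``frame, keypoint_id, u, v, confidence``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParseError, TrialUnusableError

logger = logging.getLogger(__name__)

N_KEYPOINTS = 25

__all__ = [
    "N_KEYPOINTS",
    "PoseSequence",
    "read_pose_sequence",
    "write_pose_csv",
    "write_openpose_dir",
    "fill_gaps",
]


@dataclass
class PoseSequence:
    """Per-camera time series of 25 image-plane keypoints with confidences.

    Attributes
    ----------
    camera_id : str
        Label of the camera that produced the stream.
    fs : float
        Sampling rate in Hz (cameras are assumed frame-synchronized).
    data : ndarray, shape (n_frames, 25, 3)
        ``data[t, k] = (u, v, confidence)``.  Frame indices are implicit,
        contiguous and 0-based.
    """

    camera_id: str
    fs: float
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.data.ndim != 3 or self.data.shape[1:] != (N_KEYPOINTS, 3):
            raise ValueError(
                f"data must have shape (n_frames, {N_KEYPOINTS}, 3), "
                f"got {self.data.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def confidence(self) -> np.ndarray:
        return self.data[:, :, 2]


def _parse_openpose_json(path: Path) -> np.ndarray:
    """Return the (25, 3) keypoint block of the best-detected person."""
    try:
        record = json.loads(path.read_text())
        people = record["people"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParseError(f"malformed keypoint record in {path.name}: {exc}") from exc
    if not people:
        return np.zeros((N_KEYPOINTS, 3))
    blocks = []
    for person in people:
        flat = np.asarray(person.get("pose_keypoints_2d", []), dtype=float)
        if flat.size != N_KEYPOINTS * 3:
            raise ParseError(
                f"frame {path.name}: expected {N_KEYPOINTS * 3} values per "
                f"person, got {flat.size}"
            )
        blocks.append(flat.reshape(N_KEYPOINTS, 3))
    if len(blocks) > 1:
        mean_conf = [b[:, 2].mean() for b in blocks]
        pick = int(np.argmax(mean_conf))
        logger.info(
            "%s: %d people detected, keeping person %d (mean confidence %.3f)",
            path.name, len(blocks), pick, mean_conf[pick],
        )
        return blocks[pick]
    return blocks[0]


def _read_openpose_dir(path: Path, camera_id: str, fs: float) -> PoseSequence:
    files = sorted(path.glob("*.json"))
    if not files:
        raise EmptyInputError(f"no keypoint JSON files in {path}")
    frames = [_parse_openpose_json(f) for f in files]
    return PoseSequence(camera_id=camera_id, fs=fs, data=np.stack(frames))


def _read_pose_csv(path: Path, camera_id: str, fs: float) -> PoseSequence:
    df = pd.read_csv(path)
    required = {"frame", "keypoint_id", "u", "v", "confidence"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: consolidated CSV needs columns {sorted(required)}"
        )
    if df.empty:
        raise EmptyInputError(f"{path} holds zero keypoint rows")
    frames = np.sort(df["frame"].unique())
    if frames[0] != 0 or not np.array_equal(frames, np.arange(len(frames))):
        raise ParseError(f"{path}: frame indices must be contiguous from 0")
    data = np.zeros((len(frames), N_KEYPOINTS, 3))
    rows = df[["frame", "keypoint_id", "u", "v", "confidence"]].to_numpy()
    f_idx = rows[:, 0].astype(int)
    k_idx = rows[:, 1].astype(int)
    if k_idx.min() < 0 or k_idx.max() >= N_KEYPOINTS:
        raise ParseError(f"{path}: keypoint_id outside 0..{N_KEYPOINTS - 1}")
    data[f_idx, k_idx] = rows[:, 2:5]
    return PoseSequence(camera_id=camera_id, fs=fs, data=data)


def read_pose_sequence(path: str | Path, camera_id: str, fs: float = 120.0) -> PoseSequence:
    """Read a per-camera keypoint stream from disk.

    ``path`` may be a directory of per-frame JSON files or a consolidated CSV.
    Frames with no detected person become all-zero-confidence frames; when a
    record holds several people the one with the highest mean confidence is
    kept (and the choice logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_openpose_dir(path, camera_id, fs)
    return _read_pose_csv(path, camera_id, fs)


def write_pose_csv(seq: PoseSequence, path: str | Path) -> None:
    """Write a sequence as the canonical consolidated long CSV."""
    n, k = seq.n_frames, N_KEYPOINTS
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n), k),
            "keypoint_id": np.tile(np.arange(k), n),
            "u": seq.data[:, :, 0].ravel(),
            "v": seq.data[:, :, 1].ravel(),
            "confidence": seq.data[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_openpose_dir(seq: PoseSequence, path: str | Path) -> None:
    """Write a sequence as one JSON file per frame in the detector dialect."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for t in range(seq.n_frames):
        record = {
            "version": 1.3,
            "people": [
                {"pose_keypoints_2d": seq.data[t].ravel().tolist()}
            ],
        }
        (path / f"{seq.camera_id}_{t:06d}_keypoints.json").write_text(
            json.dumps(record)
        )


def _interp_track(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Piecewise-linear fill of invalid samples; ends held at nearest valid."""
    out = values.copy()
    idx = np.arange(values.size)
    out[~valid] = np.interp(idx[~valid], idx[valid], values[valid])
    return out


def _max_gap_run(valid: np.ndarray) -> int:
    """Longest run of consecutive invalid samples."""
    worst = run = 0
    for v in valid:
        run = 0 if v else run + 1
        worst = max(worst, run)
    return worst


def fill_gaps(
    seq: PoseSequence,
    conf_min: float = 0.1,
    max_gap: int = 12,
) -> tuple[PoseSequence, pd.DataFrame]:
    """Interpolate low-confidence keypoints.

    Keypoints with confidence below ``conf_min`` are replaced by
    piecewise-linear interpolation between the nearest flanking valid frames;
    gaps touching the sequence ends are held at the nearest valid value.
    Returns the repaired sequence plus a repair log (one row per repaired
    sample, flag -1).  Defaults: ``conf_min=0.1``, ``max_gap=12`` frames
    (0.1 s at 120 Hz).

    Raises
    ------
    TrialUnusableError
        If any keypoint track contains a gap longer than ``max_gap`` frames
        (the trial should be discarded, mirroring field practice).
    """
    if not 0 < conf_min <= 1:
        raise ValueError(f"conf_min must be in (0, 1], got {conf_min}")
    if max_gap < 1:
        raise ValueError(f"max_gap must be >= 1, got {max_gap}")

    data = seq.data.copy()
    valid = data[:, :, 2] >= conf_min
    log_rows: list[tuple[int, int]] = []
    for k in range(N_KEYPOINTS):
        vk = valid[:, k]
        if vk.all():
            continue
        if not vk.any():
            raise TrialUnusableError(
                f"keypoint {k}: no frame reaches confidence {conf_min}"
            )
        gap = _max_gap_run(vk)
        if gap > max_gap:
            raise TrialUnusableError(
                f"keypoint {k}: gap of {gap} frames exceeds max_gap={max_gap}"
            )
        for axis in (0, 1):
            data[:, k, axis] = _interp_track(data[:, k, axis], vk)
        log_rows.extend((int(t), k) for t in np.nonzero(~vk)[0])

    log = pd.DataFrame(log_rows, columns=["frame", "keypoint_id"])
    log["flag"] = -1
    repaired = PoseSequence(camera_id=seq.camera_id, fs=seq.fs, data=data)
    return repaired, log
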