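"""Reading, writing, validating and trimming pose-landmark sessions.

On-disk format: a long-form CSV with one row per (frame, landmark) —
columns ``participant_id, frame_idx, landmark_idx, x, y, z, confidence``.
Coordinates are normalized image units (not clamped to [0, 1]: pose
estimators can emit slightly out-of-frame values); confidence lies in
[0, 1].  Floats are written at full round-trip precision so that
``write_session`` followed by ``read_session`` is numerically exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarks import N_LANDMARKS

SESSION_COLUMNS = ["participant_id", "frame_idx", "landmark_idx", "x", "y", "z", "confidence"]
METADATA_COLUMNS = ["participant_id", "group", "age_months", "sex", "conners_score"]

GROUPS = ("risk", "control")
SEXES = ("boy", "girl")


class MalformedSessionError(ValueError):
    """The on-disk table does not follow the documented layout."""


class SessionTooShortError(ValueError):
    """Not enough frames after the requested onset."""


@dataclass
class SessionRecording:
    """One participant's 33-landmark trajectory with confidences.

    Attributes
    ----------
    participant_id : str
    fps : float
        Frames per second (30 for the recording protocol emulated here).
    xyz : ndarray, shape (n_frames, 33, 3)
        Normalized image coordinates; z is relative depth.
    confidence : ndarray, shape (n_frames, 33)
        Per-landmark tracking confidence in [0, 1].
    """

    participant_id: str
    fps: float
    xyz: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.confidence = np.asarray(self.confidence, dtype=np.float64)
        if self.fps <= 0:
            raise MalformedSessionError(f"fps must be positive, got {self.fps}")
        if self.xyz.ndim != 3 or self.xyz.shape[1:] != (N_LANDMARKS, 3):
            raise MalformedSessionError(
                f"xyz must have shape (n_frames, {N_LANDMARKS}, 3), got {self.xyz.shape}"
            )
        if self.confidence.shape != self.xyz.shape[:2]:
            raise MalformedSessionError(
                f"confidence shape {self.confidence.shape} does not match frames "
                f"{self.xyz.shape[:2]}"
            )
        if self.n_frames and (self.confidence.min() < 0 or self.confidence.max() > 1):
            raise MalformedSessionError("confidence values outside [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def write_session(session: SessionRecording, path: str | Path, fps_comment: bool = True) -> None:
    """Write a session as long-form CSV (one row per frame and landmark).

    The fps is stored in a ``# fps=<value>`` header comment line.
    """
    path = Path(path)
    t, k = session.confidence.shape
    frame_idx = np.repeat(np.arange(t), k)
    landmark_idx = np.tile(np.arange(k), t)
    df = pd.DataFrame(
        {
            "participant_id": session.participant_id,
            "frame_idx": frame_idx,
            "landmark_idx": landmark_idx,
            "x": session.xyz[:, :, 0].ravel(),
            "y": session.xyz[:, :, 1].ravel(),
            "z": session.xyz[:, :, 2].ravel(),
            "confidence": session.confidence.ravel(),
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if fps_comment:
            fh.write(f"# fps={session.fps!r}\n")
        # shortest exact decimal: read_session restores bit-equal floats
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def read_session(path: str | Path, fps: float | None = None) -> SessionRecording:
    """Read and validate a long-form session CSV.

    Parameters
    ----------
    fps : float, optional
        Override for the frame rate; otherwise taken from the ``# fps=``
        header comment (default 30 if absent).
    """
    path = Path(path)
    header_fps = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# fps="):
            header_fps = float(first.strip().split("=", 1)[1])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedSessionError(f"{path}: missing columns {missing}")
    if fps is None:
        fps = header_fps if header_fps is not None else 30.0

    frames = np.unique(df["frame_idx"].to_numpy())
    n_frames = len(frames)
    if n_frames == 0:
        raise MalformedSessionError(f"{path}: empty session")
    if not np.array_equal(frames, np.arange(n_frames)):
        raise MalformedSessionError(
            f"{path}: frame indices must be contiguous from 0, got range "
            f"[{frames.min()}, {frames.max()}] with {n_frames} distinct values"
        )
    counts = df.groupby("frame_idx").size()
    bad = counts[counts != N_LANDMARKS]
    if len(bad):
        frame = int(bad.index[0])
        raise MalformedSessionError(
            f"{path}: frame {frame} has {int(bad.iloc[0])} landmarks, expected {N_LANDMARKS}"
        )
    df = df.sort_values(["frame_idx", "landmark_idx"], kind="mergesort")
    lm = df["landmark_idx"].to_numpy().reshape(n_frames, N_LANDMARKS)
    if not np.array_equal(lm, np.tile(np.arange(N_LANDMARKS), (n_frames, 1))):
        frame = int(np.nonzero((lm != np.arange(N_LANDMARKS)).any(axis=1))[0][0])
        raise MalformedSessionError(
            f"{path}: frame {frame} has duplicated or missing landmark indices"
        )
    xyz = np.stack(
        [df[c].to_numpy().reshape(n_frames, N_LANDMARKS) for c in ("x", "y", "z")], axis=-1
    )
    conf = df["confidence"].to_numpy().reshape(n_frames, N_LANDMARKS)
    if conf.min() < 0 or conf.max() > 1:
        raise MalformedSessionError(f"{path}: confidence outside [0, 1]")
    pid = str(df["participant_id"].iloc[0])
    return SessionRecording(participant_id=pid, fps=fps, xyz=xyz, confidence=conf)


def trim_session(
    session: SessionRecording, onset_frame: int, duration_s: float
) -> SessionRecording:
    """Return exactly ``fps * duration_s`` frames starting at ``onset_frame``.

    Frame indices are renumbered from 0.  The recording protocol trims to
    an exact 180 s window aligned to a caller-supplied onset.
    """
    n_keep = round(session.fps * duration_s)
    if onset_frame < 0:
        raise ValueError(f"onset_frame must be >= 0, got {onset_frame}")
    if onset_frame + n_keep > session.n_frames:
        raise SessionTooShortError(
            f"session {session.participant_id}: need {n_keep} frames from onset "
            f"{onset_frame} but only {session.n_frames} frames available"
        )
    return SessionRecording(
        participant_id=session.participant_id,
        fps=session.fps,
        xyz=session.xyz[onset_frame : onset_frame + n_keep].copy(),
        confidence=session.confidence[onset_frame : onset_frame + n_keep].copy(),
    )


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    """Write the participant metadata table (documented header)."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns {missing}")
    metadata[METADATA_COLUMNS].to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the participant metadata table."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedSessionError(f"{path}: metadata missing columns {missing}")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise MalformedSessionError(f"{path}: unknown group labels {sorted(bad_group)}")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise MalformedSessionError(f"{path}: unknown sex labels {sorted(bad_sex)}")
    scores = df["conners_score"].to_numpy()
    if scores.min() < 0 or scores.max() > 30:
        raise MalformedSessionError(f"{path}: conners_score outside [0, 30]")
    return df
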