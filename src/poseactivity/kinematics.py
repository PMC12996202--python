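"""Composite points, pelvis-root centering, and windowed-displacement indices.

The 33 landmarks are aggregated into 17 anatomically meaningful analysis
points (head = centroid of the 11 facial landmarks; each distal hand =
centroid of thumb/index/pinky; each distal foot = centroid of heel and
foot-index; the remaining joints map one-to-one).  All points are then
expressed in the pelvis-root frame — coordinates relative to the per-frame
midpoint of the two hip landmarks — which removes whole-body translation
and isolates segmental motion.

A regional activity index is the cumulative displacement of one centered
point: positions are averaged within consecutive non-overlapping 5-frame
windows (~167 ms at 30 fps), Euclidean displacement is taken between
successive window means using x and y only (monocular depth is unreliable,
so z never enters the indices), and the displacements are summed over the
recording.  The global activity index is the exact sum of the 17 regional
indices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import landmarks as lm
from .io import SessionRecording
from .qc import QcConfig, process_session

DEFAULT_WINDOW = 5

FEATURE_COLUMNS = list(lm.REGIONS) + [lm.GLOBAL_INDEX]


class InsufficientDataError(ValueError):
    """Series too short to form at least two analysis windows."""


def aggregate_composites(session_xyz: np.ndarray) -> np.ndarray:
    """Aggregate (T, 33, 3) landmark coordinates into (T, 17, 3) composites.

    Composite order follows :data:`poseactivity.landmarks.REGIONS`;
    centroids are unweighted means of the member landmarks.
    """
    xyz = np.asarray(session_xyz, dtype=np.float64)
    out = np.empty((xyz.shape[0], len(lm.REGIONS), 3))
    for i, region in enumerate(lm.REGIONS):
        members = list(lm.COMPOSITES[region])
        out[:, i] = xyz[:, members].mean(axis=1) if len(members) > 1 else xyz[:, members[0]]
    return out


def pelvis_center(session_xyz: np.ndarray) -> np.ndarray:
    """Per-frame pelvis root: midpoint of the left and right hip landmarks."""
    xyz = np.asarray(session_xyz, dtype=np.float64)
    return 0.5 * (xyz[:, lm.LEFT_HIP] + xyz[:, lm.RIGHT_HIP])


def root_center(composites: np.ndarray, pelvis: np.ndarray) -> np.ndarray:
    """Express composite points relative to the per-frame pelvis root."""
    composites = np.asarray(composites, dtype=np.float64)
    pelvis = np.asarray(pelvis, dtype=np.float64)
    if composites.shape[0] != pelvis.shape[0]:
        raise ValueError("composites and pelvis frame counts differ")
    return composites - pelvis[:, None, :]


def window_displacement_index(
    series: np.ndarray, window: int = DEFAULT_WINDOW
) -> float:
    """Cumulative x-y displacement between successive window-mean positions.

    ``series`` is one centered point's (T, 3) trajectory.  Frames are
    partitioned into ``floor(T / window)`` consecutive non-overlapping
    windows (trailing remainder dropped); the index is the sum of
    Euclidean distances between successive per-window mean positions,
    computed in the image plane only (z excluded).
    """
    series = np.asarray(series, dtype=np.float64)
    t = series.shape[0]
    n_win = t // window
    if n_win < 2:
        raise InsufficientDataError(
            f"need at least {2 * window} frames for window={window}, got {t}"
        )
    means = series[: n_win * window].reshape(n_win, window, -1).mean(axis=1)
    deltas = np.diff(means[:, :2], axis=0)
    return float(np.hypot(deltas[:, 0], deltas[:, 1]).sum())


def session_indices(
    session: SessionRecording, window: int = DEFAULT_WINDOW
) -> dict[str, float]:
    """All 17 regional indices plus the global index for one clean session.

    Landmarks are centered on the pelvis root before aggregation
    (algebraically identical to centering the composites, but exactly
    translation-invariant in floating point).
    """
    pelvis = pelvis_center(session.xyz)
    centered = aggregate_composites(session.xyz - pelvis[:, None, :])
    indices = {
        region: window_displacement_index(centered[:, i], window)
        for i, region in enumerate(lm.REGIONS)
    }
    indices[lm.GLOBAL_INDEX] = float(sum(indices[r] for r in lm.REGIONS))
    return indices


def build_feature_table(
    sessions: list[SessionRecording],
    metadata: pd.DataFrame,
    qc_config: QcConfig | None = None,
    window: int = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, list]:
    """Run QC and index extraction over a cohort.

    Returns ``(features, qc_records)`` where ``features`` has one row per
    retained participant: the 17 regional indices, the global index, and
    the metadata columns.  Sessions failing the QC exclusion rule are
    dropped (their QC records still appear in ``qc_records``).
    """
    qc_config = qc_config or QcConfig()
    meta = metadata.set_index("participant_id")
    rows = []
    records = []
    for session in sessions:
        cleaned, record = process_session(session, qc_config)
        records.append(record)
        if cleaned is None:
            continue
        row = {"participant_id": session.participant_id}
        row.update(session_indices(cleaned, window))
        m = meta.loc[session.participant_id]
        row.update(
            group=m["group"], age_months=int(m["age_months"]), sex=m["sex"],
            conners_score=int(m["conners_score"]),
        )
        rows.append(row)
    features = pd.DataFrame(rows)
    return features, records
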