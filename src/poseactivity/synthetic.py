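"""Synthetic seated-child pose cohorts with group-structured fidgeting.

No raw recordings are deposited for the study conditions this package
analyzes, so the cohort generator is a first-class stand-in: it emulates
the statistical structure the downstream pipeline assumes — seated
children facing the camera, group-dependent movement amplitude
concentrated in distal limb segments, frame-level pose-estimator jitter,
bursty confidence dropouts, and a teacher hyperactivity rating positively
coupled to each child's latent activity level.  It is a phenomenological
motion model, not a claim about child biomechanics.

Motion model
------------
Each body segment (per side) carries a mean-reverting (discrete
Ornstein-Uhlenbeck) planar displacement process around the base pose:

    d_t = (1 - theta) * d_{t-1} + sigma * eps_t

with per-segment noise scale ``sigma = amplitude * group multiplier *
child activity factor``.  Kinematic-chain coherence is imposed by letting
each distal segment inherit a fraction of its parent's displacement
(shoulder->elbow->wrist->hand; hip->knee->ankle->foot); the 11 facial
landmarks move rigidly with a single head process.  Independent Gaussian
jitter is added per landmark and frame.  The z coordinate is populated
with small group-independent motion.  Confidence is 1.0 outside dropout
bursts and uniform in [0, 0.5) inside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import landmarks as lm
from .io import SessionRecording

#: Seated-child base pose facing the camera, normalized image units
#: (x right, y down, z relative depth).  Left-side landmarks appear on the
#: image right (x > 0.5) as in a frontal view.
BASE_POSE: dict[int, tuple[float, float, float]] = {
    0: (0.500, 0.240, -0.05),   # nose
    1: (0.485, 0.225, -0.04), 2: (0.478, 0.225, -0.04), 3: (0.471, 0.225, -0.04),
    4: (0.515, 0.225, -0.04), 5: (0.522, 0.225, -0.04), 6: (0.529, 0.225, -0.04),
    7: (0.455, 0.235, 0.00), 8: (0.545, 0.235, 0.00),   # ears
    9: (0.488, 0.265, -0.03), 10: (0.512, 0.265, -0.03),  # mouth
    lm.LEFT_SHOULDER: (0.580, 0.380, 0.00),
    lm.RIGHT_SHOULDER: (0.420, 0.380, 0.00),
    lm.LEFT_ELBOW: (0.620, 0.480, 0.02),
    lm.RIGHT_ELBOW: (0.380, 0.480, 0.02),
    lm.LEFT_WRIST: (0.640, 0.570, 0.01),
    lm.RIGHT_WRIST: (0.360, 0.570, 0.01),
    lm.LEFT_PINKY: (0.655, 0.600, 0.01),
    lm.RIGHT_PINKY: (0.345, 0.600, 0.01),
    lm.LEFT_INDEX: (0.648, 0.608, 0.01),
    lm.RIGHT_INDEX: (0.352, 0.608, 0.01),
    lm.LEFT_THUMB: (0.638, 0.598, 0.01),
    lm.RIGHT_THUMB: (0.362, 0.598, 0.01),
    lm.LEFT_HIP: (0.560, 0.620, 0.00),
    lm.RIGHT_HIP: (0.440, 0.620, 0.00),
    lm.LEFT_KNEE: (0.585, 0.750, -0.03),
    lm.RIGHT_KNEE: (0.415, 0.750, -0.03),
    lm.LEFT_ANKLE: (0.575, 0.880, 0.02),
    lm.RIGHT_ANKLE: (0.425, 0.880, 0.02),
    lm.LEFT_HEEL: (0.570, 0.905, 0.03),
    lm.RIGHT_HEEL: (0.430, 0.905, 0.03),
    lm.LEFT_FOOT_INDEX: (0.590, 0.915, -0.01),
    lm.RIGHT_FOOT_INDEX: (0.410, 0.915, -0.01),
}

#: Control-arm per-frame OU noise scale per segment (normalized units).
DEFAULT_AMPLITUDE: dict[str, float] = {
    "head": 1.0e-3, "shoulder": 5.0e-4, "elbow": 8.0e-4, "wrist": 1.2e-3,
    "hand": 1.5e-3, "hip": 2.0e-4, "knee": 8.0e-4, "ankle": 1.2e-3, "foot": 1.5e-3,
}

#: Risk-arm multipliers: distal segments amplified most, proximal barely.
DEFAULT_RISK_MULTIPLIER: dict[str, float] = {
    "head": 1.4, "shoulder": 1.1, "elbow": 1.5, "wrist": 2.0,
    "hand": 2.0, "hip": 1.0, "knee": 1.5, "ankle": 2.0, "foot": 2.0,
}

#: Fraction of the parent segment's displacement inherited down the chain.
CHAIN_INHERITANCE: dict[str, tuple[str, float]] = {
    "elbow": ("shoulder", 0.6),
    "wrist": ("elbow", 0.7),
    "hand": ("wrist", 0.9),
    "knee": ("hip", 0.5),
    "ankle": ("knee", 0.7),
    "foot": ("ankle", 0.9),
}

#: Landmark index -> (segment, side); side is "" for midline/face.
_LANDMARK_SEGMENT: dict[int, tuple[str, str]] = {}
for _i in lm.FACE:
    _LANDMARK_SEGMENT[_i] = ("head", "")
for _seg, _left, _right in [
    ("shoulder", lm.LEFT_SHOULDER, lm.RIGHT_SHOULDER),
    ("elbow", lm.LEFT_ELBOW, lm.RIGHT_ELBOW),
    ("wrist", lm.LEFT_WRIST, lm.RIGHT_WRIST),
    ("hip", lm.LEFT_HIP, lm.RIGHT_HIP),
    ("knee", lm.LEFT_KNEE, lm.RIGHT_KNEE),
    ("ankle", lm.LEFT_ANKLE, lm.RIGHT_ANKLE),
]:
    _LANDMARK_SEGMENT[_left] = (_seg, "L")
    _LANDMARK_SEGMENT[_right] = (_seg, "R")
for _i in (lm.LEFT_PINKY, lm.LEFT_INDEX, lm.LEFT_THUMB):
    _LANDMARK_SEGMENT[_i] = ("hand", "L")
for _i in (lm.RIGHT_PINKY, lm.RIGHT_INDEX, lm.RIGHT_THUMB):
    _LANDMARK_SEGMENT[_i] = ("hand", "R")
for _i in (lm.LEFT_HEEL, lm.LEFT_FOOT_INDEX):
    _LANDMARK_SEGMENT[_i] = ("foot", "L")
for _i in (lm.RIGHT_HEEL, lm.RIGHT_FOOT_INDEX):
    _LANDMARK_SEGMENT[_i] = ("foot", "R")


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study conditions: 20 risk / 31 control children
    aged 48-60 months recorded at 30 fps for 180 s, with risk-arm motion
    amplified in distal limb segments and teacher ratings coupled
    linearly to latent activity (clipped to the 0-30 scale).
    """

    n_risk: int = 20
    n_control: int = 31
    fps: float = 30.0
    duration_s: float = 180.0
    region_amplitude: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE))
    risk_multiplier: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_MULTIPLIER))
    ou_theta: float = 0.05           # mean-reversion rate, 1/frame
    jitter_sd: float = 5.0e-4        # per-frame landmark noise, normalized units
    z_amplitude: float = 1.0e-3      # group-independent depth motion
    activity_sigma: float = 0.35     # lognormal sd of per-child activity factor
    dropout_rate: float = 0.3        # expected bursts per landmark per minute
    dropout_length_dist: float = 0.15  # geometric p; mean burst ~1/p frames
    conners_intercept: float = -7.8
    conners_slope: float = 8.8
    conners_noise_sd: float = 2.0
    age_range_months: tuple[int, int] = (48, 60)
    sex_proportions: dict[str, float] = field(
        default_factory=lambda: {"risk": 14 / 20, "control": 15 / 31})  # boys
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_risk < 0 or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")
        n_frames = self.fps * self.duration_s
        if n_frames <= 0 or abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError(
                f"fps * duration_s must be a positive integer frame count, got {n_frames}")
        missing = set(lm.SEGMENTS) - set(self.region_amplitude)
        if missing:
            raise ValueError(f"region_amplitude missing segments {sorted(missing)}")
        missing = set(lm.SEGMENTS) - set(self.risk_multiplier)
        if missing:
            raise ValueError(f"risk_multiplier missing segments {sorted(missing)}")
        for name in ("ou_theta", "jitter_sd", "z_amplitude", "dropout_rate",
                     "conners_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.region_amplitude.values()):
            raise ValueError("amplitudes must be >= 0")
        if not 0 < self.dropout_length_dist <= 1:
            raise ValueError("dropout_length_dist must lie in (0, 1]")

    @property
    def n_frames(self) -> int:
        return round(self.fps * self.duration_s)


def _ou_series(rng: np.random.Generator, t: int, n: int, theta: float,
               sigma: np.ndarray) -> np.ndarray:
    """(t, n) discrete OU displacement paths started at 0, vectorized in time."""
    noise = rng.standard_normal((t, n)) * sigma
    # AR(1): d_t = (1 - theta) d_{t-1} + noise_t
    return lfilter([1.0], [1.0, -(1.0 - theta)], noise, axis=0)


def _draw_activity(rng: np.random.Generator, sigma: float) -> float:
    return float(np.exp(rng.normal(0.0, sigma)))


def generate_session(
    spec: CohortSpec,
    group: str,
    participant_seed: int,
    participant_id: str = "sim",
    activity: float | None = None,
) -> SessionRecording:
    """Simulate one seated-child session for the given study arm.

    ``activity`` is the child's latent activity factor multiplying every
    segment amplitude; drawn lognormal(0, activity_sigma) when omitted.
    Identical arguments yield a bit-identical recording.
    """
    if group not in ("risk", "control"):
        raise ValueError(f"group must be 'risk' or 'control', got {group!r}")
    t = spec.n_frames
    if t <= 0:
        raise ValueError("non-positive frame count")
    rng = np.random.Generator(np.random.PCG64(participant_seed))
    if activity is None:
        activity = _draw_activity(rng, spec.activity_sigma)

    mult = spec.risk_multiplier if group == "risk" else {s: 1.0 for s in lm.SEGMENTS}
    # Own (pre-inheritance) OU displacement per (segment, side, axis x/y).
    keys = [(seg, side) for seg in lm.SEGMENTS for side in (("",) if seg == "head" else ("L", "R"))]
    sigma = np.array(
        [spec.region_amplitude[seg] * mult[seg] * activity for seg, _ in keys for _ax in (0, 1)]
    )
    own = _ou_series(rng, t, len(keys) * 2, spec.ou_theta, sigma)
    disp = {k: own[:, 2 * i : 2 * i + 2] for i, k in enumerate(keys)}
    # Chain inheritance: child segment carries a fraction of its parent.
    for seg in ("elbow", "wrist", "hand", "knee", "ankle", "foot"):
        parent, frac = CHAIN_INHERITANCE[seg]
        for side in ("L", "R"):
            disp[(seg, side)] = disp[(seg, side)] + frac * disp[(parent, side)]

    base = np.array([BASE_POSE[i] for i in range(lm.N_LANDMARKS)])
    xyz = np.tile(base, (t, 1, 1))
    for idx in range(lm.N_LANDMARKS):
        seg, side = _LANDMARK_SEGMENT[idx]
        xyz[:, idx, :2] += disp[(seg, side)]
    # Depth: small mean-reverting motion carrying no group signal.
    if spec.z_amplitude > 0:
        xyz[:, :, 2] += _ou_series(
            rng, t, lm.N_LANDMARKS, spec.ou_theta,
            np.full(lm.N_LANDMARKS, spec.z_amplitude))
    if spec.jitter_sd > 0:
        xyz += rng.normal(0.0, spec.jitter_sd, size=xyz.shape)

    confidence = np.ones((t, lm.N_LANDMARKS))
    if spec.dropout_rate > 0:
        minutes = spec.duration_s / 60.0
        for idx in range(lm.N_LANDMARKS):
            for _ in range(rng.poisson(spec.dropout_rate * minutes)):
                start = int(rng.integers(0, t))
                length = int(rng.geometric(spec.dropout_length_dist))
                stop = min(start + length, t)
                confidence[start:stop, idx] = rng.uniform(0.0, 0.5, size=stop - start)

    return SessionRecording(
        participant_id=participant_id, fps=spec.fps, xyz=xyz, confidence=confidence
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[SessionRecording], pd.DataFrame]:
    """Generate a full cohort: sessions plus a participant metadata table.

    Per-participant seeds derive deterministically from ``spec.seed``; the
    teacher (Conners) hyperactivity score is a clipped, rounded linear
    function of the child's realized latent activity scaled by the arm's
    mean distal multiplier, so rating and movement are positively coupled.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_risk + spec.n_control
    children = ss.spawn(n_total + 1)
    meta_rng = np.random.Generator(np.random.PCG64(children[-1]))

    groups = ["risk"] * spec.n_risk + ["control"] * spec.n_control
    sessions: list[SessionRecording] = []
    rows = []
    distal = ("wrist", "hand", "ankle", "foot")
    for i, group in enumerate(groups):
        pid = f"P{i:03d}"
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        child_rng = np.random.Generator(np.random.PCG64(children[i]))
        activity = _draw_activity(child_rng, spec.activity_sigma)
        session = generate_session(spec, group, child_seed, pid, activity=activity)
        sessions.append(session)

        mult = spec.risk_multiplier if group == "risk" else {s: 1.0 for s in lm.SEGMENTS}
        latent = activity * float(np.mean([mult[s] for s in distal]))
        score = (spec.conners_intercept + spec.conners_slope * latent
                 + meta_rng.normal(0.0, spec.conners_noise_sd))
        score = int(round(min(max(score, 0.0), 30.0)))
        p_boy = spec.sex_proportions[group]
        sex = "boy" if meta_rng.uniform() < p_boy else "girl"
        age = int(meta_rng.integers(spec.age_range_months[0], spec.age_range_months[1] + 1))
        rows.append(
            {"participant_id": pid, "group": group, "age_months": age,
             "sex": sex, "conners_score": score}
        )
    return sessions, pd.DataFrame(rows)


def null_spec(spec: CohortSpec | None = None, **overrides) -> CohortSpec:
    """A spec whose arms are exchangeable (all risk multipliers 1.0)."""
    spec = spec or CohortSpec()
    return replace(
        spec, risk_multiplier={s: 1.0 for s in lm.SEGMENTS}, **overrides
    )
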