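"""Constants for the 33-keypoint pose-landmark layout.

The layout follows the standard full-body pose-estimation convention:
facial keypoints 0-10, upper body 11-24, lower body 25-32, with even
indices on the subject's right and odd indices on the subject's left
(for paired landmarks from 11 upward).  Left/right assignments are made
here once and imported everywhere else.
"""

from __future__ import annotations

N_LANDMARKS = 33

# Facial keypoints: nose, eyes (inner/center/outer), ears, mouth corners.
FACE = tuple(range(0, 11))

LEFT_SHOULDER, RIGHT_SHOULDER = 11, 12
LEFT_ELBOW, RIGHT_ELBOW = 13, 14
LEFT_WRIST, RIGHT_WRIST = 15, 16
LEFT_PINKY, RIGHT_PINKY = 17, 18
LEFT_INDEX, RIGHT_INDEX = 19, 20
LEFT_THUMB, RIGHT_THUMB = 21, 22
LEFT_HIP, RIGHT_HIP = 23, 24
LEFT_KNEE, RIGHT_KNEE = 25, 26
LEFT_ANKLE, RIGHT_ANKLE = 27, 28
LEFT_HEEL, RIGHT_HEEL = 29, 30
LEFT_FOOT_INDEX, RIGHT_FOOT_INDEX = 31, 32

#: Composite analysis points: region name -> member landmark indices.
#: A composite is the unweighted centroid of its members.
COMPOSITES: dict[str, tuple[int, ...]] = {
    "head": FACE,
    "left_shoulder": (LEFT_SHOULDER,),
    "right_shoulder": (RIGHT_SHOULDER,),
    "left_elbow": (LEFT_ELBOW,),
    "right_elbow": (RIGHT_ELBOW,),
    "left_wrist": (LEFT_WRIST,),
    "right_wrist": (RIGHT_WRIST,),
    "left_hand": (LEFT_THUMB, LEFT_INDEX, LEFT_PINKY),
    "right_hand": (RIGHT_THUMB, RIGHT_INDEX, RIGHT_PINKY),
    "left_hip": (LEFT_HIP,),
    "right_hip": (RIGHT_HIP,),
    "left_knee": (LEFT_KNEE,),
    "right_knee": (RIGHT_KNEE,),
    "left_ankle": (LEFT_ANKLE,),
    "right_ankle": (RIGHT_ANKLE,),
    "left_foot": (LEFT_HEEL, LEFT_FOOT_INDEX),
    "right_foot": (RIGHT_HEEL, RIGHT_FOOT_INDEX),
}

#: Canonical order of the 17 analysis regions.
REGIONS: tuple[str, ...] = tuple(COMPOSITES)

#: Regions entering group statistics and correlation tables (hips excluded:
#: they are near-degenerate in the pelvis-root frame).
STAT_REGIONS: tuple[str, ...] = tuple(
    r for r in REGIONS if r not in ("left_hip", "right_hip")
)

#: Feature columns used by the classifiers (same 15 regions; the global
#: index is additionally excluded as a pure linear combination).
ML_FEATURES: tuple[str, ...] = STAT_REGIONS

GLOBAL_INDEX = "global"

#: Anatomically defined families for domain-wise Bonferroni correction.
#: The five domains partition the 17 regions (head alone; each limb as
#: proximal-to-distal chain of four including the hip/shoulder).
DOMAINS: dict[str, tuple[str, ...]] = {
    "head": ("head",),
    "right_upper_limb": ("right_shoulder", "right_elbow", "right_wrist", "right_hand"),
    "left_upper_limb": ("left_shoulder", "left_elbow", "left_wrist", "left_hand"),
    "right_lower_limb": ("right_hip", "right_knee", "right_ankle", "right_foot"),
    "left_lower_limb": ("left_hip", "left_knee", "left_ankle", "left_foot"),
}

#: Motion segments used by the synthetic generator (side-symmetric).
SEGMENTS: tuple[str, ...] = (
    "head", "shoulder", "elbow", "wrist", "hand", "hip", "knee", "ankle", "foot",
)
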