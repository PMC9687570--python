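"""The 68-slot facial landmark layout shared across the package.

The slot numbering follows the common 68-point annotation scheme used by
2D landmark detectors: 0-16 jaw line, 17-26 brows, 27-35 nose, 36-47 eyes,
48-67 mouth.  The synthetic head generator places a vertex at each slot,
and the landmark loss uses the mouth/nose slots for its default weights
(weight 20 on mouth and nose points, 0 elsewhere, overridable).

Eyelid pairs list (upper, lower) slot ids used by the eye-closure loss.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "N_LANDMARKS",
    "LANDMARK_GROUPS",
    "MOUTH_NOSE_IDS",
    "EYELID_PAIRS",
    "default_landmark_weights",
    "landmark_directions",
]

N_LANDMARKS = 68

LANDMARK_GROUPS: dict[str, range] = {
    "jaw": range(0, 17),
    "right_brow": range(17, 22),
    "left_brow": range(22, 27),
    "nose": range(27, 36),
    "right_eye": range(36, 42),
    "left_eye": range(42, 48),
    "mouth": range(48, 68),
}

MOUTH_NOSE_IDS: tuple[int, ...] = tuple(LANDMARK_GROUPS["nose"]) + tuple(
    LANDMARK_GROUPS["mouth"]
)

#: (upper eyelid slot, lower eyelid slot) pairs, right eye then left eye.
EYELID_PAIRS: tuple[tuple[int, int], ...] = ((37, 41), (38, 40), (43, 47), (44, 46))


def default_landmark_weights(n: int = N_LANDMARKS) -> np.ndarray:
    """Per-landmark weights: 20 on mouth and nose slots, 0 elsewhere."""
    w = np.zeros(n)
    for i in MOUTH_NOSE_IDS:
        if i < n:
            w[i] = 20.0
    return w


def _sph(az_deg: np.ndarray, el_deg: np.ndarray) -> np.ndarray:
    """Unit directions from azimuth (from +z toward +x) and elevation."""
    az = np.radians(np.asarray(az_deg, dtype=float))
    el = np.radians(np.asarray(el_deg, dtype=float))
    return np.column_stack(
        [np.cos(el) * np.sin(az), np.sin(el), np.cos(el) * np.cos(az)]
    )


def landmark_directions() -> np.ndarray:
    """68 unit directions on the front of a head-shaped ellipsoid.

    +z is the facing direction, +x the subject's left in image terms,
    +y up.  Positions are schematic (jaw rim, brows, nose bridge and
    nostrils, two eye rings, outer/inner mouth rings) — enough to exercise
    pose estimation and the group-weighted losses, not anatomy.
    """
    az, el = [], []

    # jaw: ear-to-ear sweep dipping to the chin
    t = np.linspace(-1.0, 1.0, 17)
    az.extend(75.0 * t)
    el.extend(-60.0 * np.cos(t * np.pi / 2.0))

    # brows
    az.extend(np.linspace(55, 15, 5))
    el.extend([25.0] * 5)
    az.extend(np.linspace(-15, -55, 5))
    el.extend([25.0] * 5)

    # nose: bridge (27-30) then nostril row (31-35)
    az.extend([0.0, 0.0, 0.0, 0.0])
    el.extend([15.0, 10.0, 5.0, 0.0])
    az.extend(np.linspace(-12, 12, 5))
    el.extend([-8.0] * 5)

    # eyes: hexagons, ordering corner/upper/upper/corner/lower/lower
    for centre in (30.0, -30.0):
        az.extend(centre + np.array([-8.0, -4.0, 4.0, 8.0, 4.0, -4.0]))
        el.extend(12.0 + np.array([0.0, 5.0, 5.0, 0.0, -5.0, -5.0]))

    # mouth: outer ring of 12, inner ring of 8
    ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    az.extend(14.0 * np.cos(ang))
    el.extend(-25.0 + 8.0 * np.sin(ang))
    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    az.extend(8.0 * np.cos(ang))
    el.extend(-25.0 + 4.0 * np.sin(ang))

    dirs = _sph(np.array(az), np.array(el))
    assert dirs.shape == (N_LANDMARKS, 3)
    return dirs
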