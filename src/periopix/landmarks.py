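"""Canonical periocular landmark set.

Ten landmarks per face, five per eye, ordered with the subject's right eye
first. "Right"/"left" are anatomical (the subject's right eye appears on the
left of a frontal photograph). Coordinates are sub-pixel, 0-based, with the
origin at the centre of the top-left pixel, x rightward and y downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Canonical index order. Indices 0-4 are the subject's right eye, 5-9 the left.
LANDMARK_NAMES: tuple[str, ...] = (
    "right_pupil_centre",
    "right_upper_lid_midpoint",
    "right_lower_lid_midpoint",
    "right_medial_canthus",
    "right_lateral_canthus",
    "left_pupil_centre",
    "left_upper_lid_midpoint",
    "left_lower_lid_midpoint",
    "left_medial_canthus",
    "left_lateral_canthus",
)

N_LANDMARKS = len(LANDMARK_NAMES)

# index aliases used throughout the measurement code
R_PUPIL, R_UPPER, R_LOWER, R_MEDIAL, R_LATERAL = 0, 1, 2, 3, 4
L_PUPIL, L_UPPER, L_LOWER, L_MEDIAL, L_LATERAL = 5, 6, 7, 8, 9

#: Index permutation applied when an image is mirrored horizontally: the two
#: eye blocks swap wholesale while per-eye roles (pupil, lids, medial/lateral
#: canthus) are preserved.
FLIP_PERMUTATION = np.array([5, 6, 7, 8, 9, 0, 1, 2, 3, 4])


@dataclass
class LandmarkSet:
    """Ten named sub-pixel 2D points for one face, in image coordinates.

    Parameters
    ----------
    points
        Array of shape (10, 2) holding (x, y) pixel coordinates in the
        canonical order of :data:`LANDMARK_NAMES`.
    """

    points: np.ndarray = field()

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"LandmarkSet requires shape ({N_LANDMARKS}, 2); got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError("LandmarkSet coordinates must all be finite")
        self.points = pts

    def __len__(self) -> int:
        return N_LANDMARKS

    def __getitem__(self, idx: int) -> np.ndarray:
        return self.points[idx]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            name: (float(x), float(y))
            for name, (x, y) in zip(LANDMARK_NAMES, self.points)
        }

    @classmethod
    def from_dict(cls, mapping: dict[str, tuple[float, float]]) -> "LandmarkSet":
        missing = [n for n in LANDMARK_NAMES if n not in mapping]
        if missing:
            raise ValidationError(f"missing landmarks: {missing}")
        pts = np.array([mapping[n] for n in LANDMARK_NAMES], dtype=float)
        return cls(pts)

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        """Apply a 3x3 homogeneous affine matrix to all points."""
        m = np.asarray(matrix, dtype=float)
        homo = np.hstack([self.points, np.ones((N_LANDMARKS, 1))])
        out = homo @ m.T
        return LandmarkSet(out[:, :2] / out[:, 2:3])

    def flipped(self, image_width: int) -> "LandmarkSet":
        """Mirror about the vertical image axis and swap the eye blocks."""
        pts = self.points.copy()
        pts[:, 0] = (image_width - 1) - pts[:, 0]
        return LandmarkSet(pts[FLIP_PERMUTATION])

    def interpupillary_px(self) -> float:
        """Euclidean distance between the two pupil centres, in pixels."""
        return float(np.linalg.norm(self.points[R_PUPIL] - self.points[L_PUPIL]))
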